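# Methods

This note records the statistical model, the synthetic-data design, the
numerical choices, and the places where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Phenometrics: seasonal curves and events

**Model.** For one taxon x plot x year, total catch per emptying interval is
Poisson with log mean = spline(day) + log(trap-days). The spline is a cubic
regression spline with 4 basis functions — stiff enough that a univoltine
pulse is smoothed, flexible enough to place and scale it. Basis functions
are the cardinal natural cubic splines on knots at the quantiles (0, 1/3,
2/3, 1) of the interval midpoints, extended linearly beyond the boundary
knots; they sum to one everywhere, so the basis spans constants and no
separate intercept is used (adding one is exactly collinear). Modelling
interval totals with a log(trap-days) exposure is the count-level equivalent
of smoothing the per-trap-per-day abundance assigned to interval midpoints;
the midpoint convention is unbiased for symmetric pulses.

**Fitting.** Poisson ML by iteratively reweighted least squares (a ~10-line
Newton scoring loop). This replaces a generic GLM call purely for
throughput — the end-to-end replication study fits ~150k curves — and a unit
test pins both the solver (against statsmodels GLM on the same design) and
the basis (against a patsy `cr` fit, same knots, fitted curves equal to
1e-4). Non-convergence or a singular system raises and the series is
excluded with a logged reason.

**Events.** Onset/peak/end are the days at which the cumulative area under
the fitted curve (trapezoid rule on a 0.1-day grid spanning first to last
trapping day) reaches 10/50/90% of its total; crossings are linearly
interpolated. The three events are automatically ordered because the
cumulative integral is non-decreasing.

**Inclusion filters** (all thresholds config-exposed):

* `low_abundance` — fewer than 50 individuals of the taxon that year summed
  across plots;
* `short_presence` — individuals in fewer than 2 emptying intervals;
* `multimodal` — more than one interior local maximum taller than 5% of the
  curve peak, **or** an interior dip (a local minimum with a >5%-of-peak
  rise on both sides). The dip clause exists because a 4-function spline
  renders two well-separated pulses as a U/W shape rather than as two clean
  interior maxima; without it bimodal seasons pass undetected.
* `asymmetric` — (peak − onset)/(end − peak) outside [1/3, 3]. The published
  screen is qualitative ("a plausible seasonal curve"); this numeric rule is
  a stand-in and is labelled as such.
* `truncated` — fitted density at the first or last trapping day exceeds 50%
  of the curve maximum (the season started or ended during peak activity).

## 2. Climate cues

**Snowmelt from depth.** The day the station snow depth falls below 10 cm
and stays below until late season (day 250); the crossing is linearly
interpolated between daily readings, and a transient one-day dip does not
count as melt-out. A series that never reaches 10 cm raises `LowSnowError`,
signalling the fallback.

**Zero-curtain fallback.** On the 0/5/10 cm depth-averaged soil series, the
longest late-winter run of days with |mean| ≤ 0.5 °C and within-day range
≤ 0.5 °C is the zero-curtain; melt-out is the first subsequent day whose
range exceeds 1.0 °C. The two tolerance values are operational choices
(config-exposed); the published account defers the details to prior work.

**Temperature window.** For one event series, the anchor is
round(mean − SD) of the event days across years and the predictor is each
year's mean air temperature over the fixed 30-day day-of-year window ending
at the anchor. A fixed, shared window was chosen over year-specific
anchoring because a year-specific anchor would require the event being
predicted. Daily-mean temperatures are used (whether the original used
hourly or daily aggregation is unstated).

**Collinearity.** VIF_j = 1/(1 − R²_j) per predictor from OLS on the others;
perfect collinearity reports `inf`.

## 3. Breakpoint regression and calibrated inference

The two-segment model is fitted by exhaustive Gaussian-ML search over
candidate breakpoints at observed cue values with at least `min_segment = 3`
points strictly on each side (the minimum giving a defined slope plus a
residual degree of freedom per segment; config-exposed). Likelihood ties
break toward the smallest k. The profile log-likelihood uses σ̂² = SSE/n; a
perfect fit (SSE below 1e-12 of the response scale) is treated as infinite
likelihood, and the observed LLR is 0 when both models are perfect.

**Null calibration.** n_null responses are simulated from the fitted
no-breakpoint model (predictors fixed, Gaussian errors at the null ML σ²);
each is refitted with both models, re-searching the breakpoint every time.
p = (1 + #{null LLR ≥ observed}) / (n_valid + 1) — the add-one form keeps
p > 0 and differs from the raw exceedance proportion by at most
1/(n_null + 1). SEs of β₁ and β₂ are SDs across the null refits. Failed
refits are dropped and counted; more than 5% failures is an error. The
simulations share the observed design, so the search is vectorised (one QR
per candidate k, all simulated responses at once); a test pins the
vectorised path to the scalar fit column by column.

Two properties of this calibration are worth stating because they are easy
to get wrong:

* the naive conditional SE of β₂ at the selected k ignores the search and
  underestimates the null-simulation SE (the motivation for calibrating);
* the null-simulation SD of β₁ is **not** close to the full-data OLS slope
  SE — β₁ is re-estimated from the (often short) first segment of every
  refit, and its spread is several times the OLS SE. The test suite asserts
  the true inequality rather than approximate equality.

## 4. Multilevel meta-regression

Effect sizes (per-series β₁ or β₂, variance = squared calibrated SE) are
pooled by REML in the model estimate_i = μ (+ moderator) + u_taxon + u_plot
+ u_taxon×plot + ε_i with known ε variances. The restricted likelihood is
maximised directly over the variance components with L-BFGS-B (bounds at
zero, three starting points including zero and a moment-based scale);
problem sizes are tens-to-hundreds of records, so dense Cholesky algebra is
ample. The log-likelihood includes the + ½log|XᵀX| constant of the
lme/metafor convention, and one test checks μ̂, SE, variance components and
logLik against metafor's `rma.mv` on a fixture. CIs are Wald-normal
(±1.96 SE) matching the symmetric published intervals; Knapp–Hartung is a
possible extension, not implemented. Q is Cochran's weighted residual sum
of squares at fixed-effect weights 1/v_i against χ²(n − p). LRTs on random
terms use REML with identical fixed effects and the naive χ²(df) reference,
conservative at the τ² = 0 boundary (the 50:50 mixture would halve p).
Moderator meta-regressions retain the full random structure — whether the
original did is unstated; the assumption is recorded here.

## 5. Synthetic data

The generator emulates a high-Arctic monitoring design: 7 plots, 4 traps
each, weekly emptying on a fixed calendar grid from the plot's snowmelt to
day 243, 28 years.

* **Climate.** Air temperature = seasonal sinusoid (winter −20 °C, summer
  +7 °C, peak day 196) + a year anomaly of −0.04 °C per day of snowmelt
  delay + daily N(0, 2 °C) noise. The anomaly term induces the
  snowmelt–temperature correlation (about −0.65 for the 30-day pre-season
  window under the defaults) that motivates fitting both cues. Snow depth is
  piecewise linear: plateau at 80 cm, spring ramp at 2.5 cm/day crossing
  10 cm exactly on the year's true melt day, bare ground the next day,
  autumn re-accumulation from day 280. Soil temperature at 0/5/10 cm is
  clamped to 0 ± 0.1 °C with near-zero within-day range while snow lies (the
  zero-curtain) and follows a depth-damped air signal with >1 °C within-day
  range once bare — so both snowmelt estimators are testable against the
  same truth.
* **Phenology.** True event days come from a piecewise-linear reaction norm
  anchored at the breakpoint (defaults: breakpoint at day-of-year 158,
  i.e. ≈ the 40th percentile of snowmelt dates; slope 0.1 before, 0.9
  after; residual SD 3 days), with the Gaussian event-day residual at the
  phenology level, not the count level — the regression module's error
  assumptions hold by construction. Latent activity is a Gaussian density
  centred on the true peak (10–90% half-width 10 days), so true
  onset/peak/end are exactly symmetric.
* **Counts.** Poisson draws per trap of the activity mass in each emptying
  interval, scaled to 300 expected individuals per taxon x plot x year
  (within-season mass; activity before trap deployment is left-truncated,
  deliberately, as a stress test).
* **Community.** `community_norms` draws taxon-level norms around community
  means: slope_pre ~ N(0, 0.1), Δslope ~ N(0.8, 0.3), baselines spread over
  the season, plus plot-level snowmelt offsets (±5 days in the acceptance
  configuration). The heterogeneity ratio (Δ-slope spread ≈ 3x the slope-1
  spread) mirrors the structure of the published community-level standard
  errors; a community of identical taxa would both contradict the reported
  strong taxon/plot heterogeneity and shrink the pooled CIs below the
  intrinsic small-sample bias of ML breakpoint selection (the selection
  effect biases β₁ slightly negative and β₂ slightly positive when noise is
  non-negligible — an inherent property of the estimator, visible in any
  replication of it).

What the generator does **not** emulate: real species composition,
multivoltinism, trap-type differences, observation gaps, autocorrelated
residuals, or spatial climate gradients beyond a static plot offset. Passing
tests therefore demonstrate correctness of the inferential machinery under
the model's own assumptions, not robustness to their violation.

## 6. Simulation-study settings

The calibration study runs at desk scale by default: 300–500 outer
replicates and 200 null simulations per fit (the published analysis used
1000; paper-scale settings are reachable via the grid/config). The
SE-underestimation demonstration uses an evenly spaced cue gradient rather
than Gaussian-sampled cues: with random Gaussian cues, candidate breakpoints
in the sparse tails occasionally have enormous conditional SEs, which
obscures (in ~10–15% of fixtures) the selection effect the demonstration is
about. Type-I and power studies keep Gaussian cues.

Problem sizes used by the test suite: type-I at n = 25 with 500 replicates;
coverage at 12 taxa x 7 plots with 400 replicates; the end-to-end study at
15 taxa x 7 plots x 28 years with 50 pipeline replicates and n_null = 200.

## 7. Determinism

Every stochastic routine takes a seed or Generator. Pipeline stages derive
one substream per series by CRC32-hashing the series labels against the
master seed, so results are independent of iteration order and of which
other series exist. Pipeline CSVs are written at %.17g and re-read with
exact float parsing, making staged CLI runs byte-identical to in-memory
runs.

## 8. Known limitations

* ML breakpoint selection is biased in small samples (β₁ down, β₂ up, both
  → 0 as noise → 0); the calibration fixes test size, not point bias.
* The Wald-normal meta CI mildly undercovers with few taxa; measured 94–95%
  at the tested designs.
* The asymmetry/multimodality screens are numeric stand-ins for a
  qualitative published rule.
* LRTs at the variance boundary are conservative.
* The breakpoint is restricted to observed cue values (as specified), so k
  is only identified up to the local cue spacing.
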