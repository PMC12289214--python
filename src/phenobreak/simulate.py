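"""Synthetic climate series and trap-catch tables with known ground truth.

The generator emulates a high-Arctic monitoring design: seven plots sampled
with a handful of pitfall traps each, emptied weekly on fixed calendar dates
from snowmelt until autumn freeze-up, with univoltine taxa whose single
seasonal activity pulse is timed by the snowmelt date and a pre-season
temperature window through a piecewise-linear reaction norm.

Three layers, each with explicit ground truth kept alongside the data:

* climate — daily air temperature (seasonal sinusoid + year anomaly tied to
  the snowmelt date + daily noise), snow depth (accumulation plateau, linear
  melt ramp crossing 10 cm on the true snowmelt day, bare ground in summer),
  and soil temperature at 0/5/10 cm clamped to ~0 deg C while snow-covered
  (the "zero-curtain") and tracking a damped air signal afterwards;
* phenology — per taxon x plot x year, true event days from the reaction
  norm applied to that year's cues plus Gaussian residual noise; latent daily
  activity is a Gaussian curve centred on the true peak, so onset/peak/end
  (10/50/90% of cumulative activity) are symmetric around the peak;
* counts — Poisson draws per trap of the latent activity integrated over
  each weekly emptying interval.

The event-day residual lives at the phenology level (not the count level),
so the breakpoint regression's Gaussian-error assumption holds by
construction and parameter recovery is a clean test of the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import as_generator

__all__ = [
    "ClimateScenario",
    "ReactionNorm",
    "TrapDesign",
    "ClimateData",
    "RegressionSet",
    "community_norms",
    "generate_climate",
    "generate_counts",
    "generate_regression_set",
]

#: 10-90% half-width of a Gaussian in units of its SD.
_Z90 = float(stats.norm.ppf(0.90))

SNOW_THRESHOLD_CM = 10.0  # depth below which ground is considered melting out
_DEPTH_MAX_CM = 80.0
_MELT_RATE = 2.5  # cm/day on the spring ramp above the threshold
_AUTUMN_START = 280
_AUTUMN_RATE = 0.8


@dataclass
class ClimateScenario:
    """Inter-annual climate variation for the synthetic site.

    ``temp_offset_per_snowmelt_day`` couples the annual temperature anomaly
    to the snowmelt date (deg C per day of snowmelt delay); a negative value
    makes late-melt years cold, inducing the snowmelt-temperature
    correlation that motivates fitting both cues together.
    """

    seed: int
    years: tuple = tuple(range(1996, 2024))
    snowmelt_mean: float = 160.0
    snowmelt_sd: float = 8.0
    temp_offset_per_snowmelt_day: float = -0.04
    daily_temp_noise_sd: float = 2.0
    winter_min: float = -20.0
    summer_max: float = 7.0
    summer_peak_day: float = 196.0
    soil_damping: float = 0.5

    def __post_init__(self):
        if self.snowmelt_sd < 0:
            raise ValueError("snowmelt_sd must be >= 0")
        if not 0 < self.soil_damping <= 1:
            raise ValueError("soil_damping must be in (0, 1]")
        if self.daily_temp_noise_sd < 0:
            raise ValueError("daily_temp_noise_sd must be >= 0")
        if len(self.years) == 0:
            raise ValueError("years must be non-empty")
        self.years = tuple(int(y) for y in self.years)


@dataclass
class ReactionNorm:
    """Piecewise-linear mapping from climate cues to an event day.

    The event day at cue ``x1`` (with optional second cue ``x2``) is::

        baseline_event_day + slope_pre * (x1 - breakpoint)
                           + delta_slope * max(x1 - breakpoint, 0)
                           + covariate_slope * x2 + N(0, residual_sd)

    i.e. ``baseline_event_day`` anchors the norm at the breakpoint, and
    ``delta_slope = 0`` collapses to a straight line.  ``event_spread`` is
    the half-width from onset (10% of activity) to peak, equal to peak to
    end by symmetry of the latent Gaussian activity curve.
    """

    baseline_event_day: float = 185.0
    slope_pre: float = 0.1
    delta_slope: float = 0.8
    breakpoint: float = 158.0
    covariate_slope: float = 0.0
    event_spread: float = 10.0
    residual_sd: float = 3.0

    def __post_init__(self):
        if self.event_spread <= 0:
            raise ValueError("event_spread must be > 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")

    @property
    def activity_sd(self) -> float:
        """SD of the latent Gaussian activity curve implied by the spread."""
        return self.event_spread / _Z90

    def event_day(self, x1, x2=0.0):
        """Noise-free event (peak) day at cues ``x1`` (and ``x2``)."""
        x1 = np.asarray(x1, dtype=float)
        return (
            self.baseline_event_day
            + self.slope_pre * (x1 - self.breakpoint)
            + self.delta_slope * np.maximum(x1 - self.breakpoint, 0.0)
            + self.covariate_slope * np.asarray(x2, dtype=float)
        )


@dataclass
class TrapDesign:
    """Trap layout and emptying schedule.

    Emptying dates sit on a fixed weekly calendar grid (doys congruent to
    ``grid_anchor_doy`` mod ``emptying_interval``); each plot's season runs
    from its snowmelt date (traps cannot operate under snow) to
    ``season_end_day``.  ``plot_snowmelt_offsets`` shifts each plot's
    melt-out relative to the station value (zeros by default).
    """

    n_plots: int = 7
    traps_per_plot: int = 4
    emptying_interval: int = 7
    grid_anchor_doy: int = 5
    season_end_day: int = 243
    mean_total_catch: float = 300.0
    plot_snowmelt_offsets: tuple | None = None

    def __post_init__(self):
        if self.traps_per_plot < 1:
            raise ValueError("traps_per_plot must be >= 1")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if self.emptying_interval < 1:
            raise ValueError("emptying_interval must be >= 1")
        if self.mean_total_catch < 0:
            raise ValueError("mean_total_catch must be >= 0")
        if self.plot_snowmelt_offsets is None:
            self.plot_snowmelt_offsets = tuple([0.0] * self.n_plots)
        elif len(self.plot_snowmelt_offsets) != self.n_plots:
            raise ValueError("plot_snowmelt_offsets must have one entry per plot")


@dataclass
class ClimateData:
    """Generated climate bundle; ``snowmelt_true`` is the generator truth."""

    air: pd.DataFrame  # year, doy, t_mean
    snow: pd.DataFrame  # year, doy, depth_cm
    soil: pd.DataFrame  # year, doy, depth_cm, t_mean, t_range
    snowmelt_true: dict

    def write_csv(self, outdir):
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.air.to_csv(outdir / "air_temperature.csv", index=False, float_format="%.17g")
        self.snow.to_csv(outdir / "snow_depth.csv", index=False, float_format="%.17g")
        self.soil.to_csv(outdir / "soil_temperature.csv", index=False, float_format="%.17g")
        pd.DataFrame(
            {"year": list(self.snowmelt_true), "snowmelt_doy": list(self.snowmelt_true.values())}
        ).to_csv(outdir / "snowmelt_true.csv", index=False, float_format="%.17g")


def generate_climate(scenario: ClimateScenario) -> ClimateData:
    """Daily air, snow-depth and soil series for every scenario year.

    Snow depth declines linearly through spring and crosses 10 cm exactly on
    the year's true snowmelt day, reaching bare ground the next day; soil
    temperature is pinned to 0 +/- 0.1 deg C while snow lies (zero-curtain)
    and fluctuates with a damped air signal once the ground is bare.
    """
    rng = as_generator(scenario.seed)
    doy = np.arange(1, 366)
    mid = 0.5 * (scenario.winter_min + scenario.summer_max)
    amp = 0.5 * (scenario.summer_max - scenario.winter_min)
    seasonal = mid + amp * np.cos(2 * np.pi * (doy - scenario.summer_peak_day) / 365.0)

    air_rows, snow_rows, soil_rows = [], [], []
    snowmelt_true = {}
    for year in scenario.years:
        melt = int(round(rng.normal(scenario.snowmelt_mean, scenario.snowmelt_sd)))
        snowmelt_true[year] = melt
        anomaly = scenario.temp_offset_per_snowmelt_day * (melt - scenario.snowmelt_mean)
        t_air = seasonal + anomaly + rng.normal(0.0, scenario.daily_temp_noise_sd, doy.size)
        air_rows.append(pd.DataFrame({"year": year, "doy": doy, "t_mean": t_air}))

        # spring ramp hits the 10 cm threshold on the melt day, bare next day
        depth = np.where(
            doy <= melt,
            np.minimum(_DEPTH_MAX_CM, SNOW_THRESHOLD_CM + _MELT_RATE * (melt - doy)),
            np.maximum(0.0, SNOW_THRESHOLD_CM * (1.0 - (doy - melt))),
        )
        autumn = np.maximum(0.0, _AUTUMN_RATE * (doy - _AUTUMN_START))
        depth = np.maximum(depth, np.minimum(_DEPTH_MAX_CM, autumn))
        snow_rows.append(pd.DataFrame({"year": year, "doy": doy, "depth_cm": depth}))

        covered = depth > 0.0
        for depth_cm in (0, 5, 10):
            damp = scenario.soil_damping ** (1.0 + depth_cm / 10.0)
            t_soil = np.where(covered, rng.uniform(-0.1, 0.1, doy.size), damp * t_air)
            t_range = np.where(
                covered,
                rng.uniform(0.0, 0.2, doy.size),
                4.0 * damp + np.abs(rng.normal(0.0, 0.3, doy.size)),
            )
            soil_rows.append(
                pd.DataFrame(
                    {"year": year, "doy": doy, "depth_cm": depth_cm,
                     "t_mean": t_soil, "t_range": t_range}
                )
            )

    return ClimateData(
        air=pd.concat(air_rows, ignore_index=True),
        snow=pd.concat(snow_rows, ignore_index=True),
        soil=pd.concat(soil_rows, ignore_index=True),
        snowmelt_true=snowmelt_true,
    )


def _emptying_dates(design: TrapDesign, season_start: float) -> np.ndarray:
    """Fixed-grid emptying dates covering (season_start, season_end_day]."""
    step = design.emptying_interval
    first = design.grid_anchor_doy + step * int(
        np.ceil((season_start - design.grid_anchor_doy) / step)
    )
    if first <= season_start:
        first += step
    return np.arange(first, design.season_end_day + 1, step, dtype=float)


def temperature_cue(climate: ClimateData, scenario: ClimateScenario) -> dict:
    """Generator-side temperature cue: mean air temperature in the fixed
    30-day window ending 10 days before the average snowmelt date."""
    hi = scenario.snowmelt_mean - 10.0
    lo = hi - 30.0
    sub = climate.air[(climate.air.doy >= lo) & (climate.air.doy < hi)]
    return sub.groupby("year")["t_mean"].mean().to_dict()


def generate_counts(
    climate: ClimateData,
    norms: dict,
    design: TrapDesign,
    seed,
):
    """Poisson trap catches for every taxon x plot x year.

    Returns ``(counts, truth)``: the long-format trap table (taxon, plot,
    year, interval_start_doy, interval_end_doy, trap_id, count) and a truth
    table with the cues and noise-free/noisy event days actually used, for
    parameter-recovery tests.

    Raises if any taxon's true peak falls outside the trapping season in
    more than half of the years (a misconfigured scenario, not a sampling
    outcome).
    """
    rng = as_generator(seed)
    years = sorted(climate.snowmelt_true)
    scenario_mean = float(np.mean(list(climate.snowmelt_true.values())))
    # temperature cue, centred across years so covariate_slope acts on anomalies
    hi = scenario_mean - 10.0
    sub = climate.air[(climate.air.doy >= hi - 30.0) & (climate.air.doy < hi)]
    temp_by_year = sub.groupby("year")["t_mean"].mean()
    temp_anom = (temp_by_year - temp_by_year.mean()).to_dict()

    chunks = []
    truth_rows = []
    n_traps = design.traps_per_plot
    trap_labels = np.array([f"trap{t + 1}" for t in range(n_traps)])
    for taxon, norm in norms.items():
        sd_act = norm.activity_sd
        n_outside = 0
        n_cells = 0
        for p in range(design.n_plots):
            plot = f"plot{p + 1}"
            offset = design.plot_snowmelt_offsets[p]
            for year in years:
                x1 = climate.snowmelt_true[year] + offset
                x2 = temp_anom[year]
                peak_nf = float(norm.event_day(x1, x2))
                peak = peak_nf + rng.normal(0.0, norm.residual_sd)
                dates = _emptying_dates(design, x1)
                n_cells += 1
                if dates.size < 2:
                    n_outside += 1
                    continue
                starts = dates[:-1]
                ends = dates[1:]
                if not (starts[0] <= peak <= ends[-1]):
                    n_outside += 1
                per_trap = design.mean_total_catch / n_traps
                mass = stats.norm.cdf(ends, peak, sd_act) - stats.norm.cdf(starts, peak, sd_act)
                counts_mat = rng.poisson(np.tile(per_trap * mass, (n_traps, 1)))
                m = starts.size
                chunks.append(
                    (taxon, plot, year, np.tile(starts, n_traps), np.tile(ends, n_traps),
                     np.repeat(trap_labels, m), counts_mat.ravel())
                )
                truth_rows.append(
                    (taxon, plot, year, x1, x2, peak_nf, peak,
                     peak - norm.event_spread, peak + norm.event_spread)
                )
        if n_outside > 0.5 * n_cells:
            raise ValueError(
                f"true peak outside the trapping season in {n_outside}/{n_cells} "
                f"cells for taxon {taxon!r}; scenario is misconfigured"
            )

    if not chunks:
        raise ValueError("no trapping intervals generated; check season settings")
    sizes = [c[3].size for c in chunks]
    counts = pd.DataFrame(
        {
            "taxon": np.repeat([c[0] for c in chunks], sizes),
            "plot": np.repeat([c[1] for c in chunks], sizes),
            "year": np.repeat([c[2] for c in chunks], sizes),
            "interval_start_doy": np.concatenate([c[3] for c in chunks]),
            "interval_end_doy": np.concatenate([c[4] for c in chunks]),
            "trap_id": np.concatenate([c[5] for c in chunks]),
            "count": np.concatenate([c[6] for c in chunks]).astype(int),
        }
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["taxon", "plot", "year", "snowmelt_cue", "temp_cue",
                 "true_peak_noisefree", "true_peak", "true_onset", "true_end"],
    )
    return counts, truth


def community_norms(
    n_taxa: int,
    seed,
    slope_pre_mean: float = 0.0,
    slope_pre_sd: float = 0.1,
    delta_slope_mean: float = 0.8,
    delta_slope_sd: float = 0.3,
    breakpoint: float = 158.0,
    baseline_range: tuple = (180.0, 215.0),
    event_spread: float = 10.0,
    residual_sd: float = 3.0,
) -> dict:
    """Draw a community of taxon-specific reaction norms.

    Taxa share the breakpoint position but differ in first-segment slope and
    slope difference (Gaussian around the community means) and in baseline
    phenology (evenly spread over the season) — the between-taxon
    heterogeneity that a multilevel meta-analysis is there to absorb.
    """
    rng = as_generator(seed)
    baselines = np.linspace(*baseline_range, n_taxa)
    norms = {}
    for i in range(n_taxa):
        norms[f"taxon{i + 1:02d}"] = ReactionNorm(
            baseline_event_day=float(baselines[i]),
            slope_pre=float(rng.normal(slope_pre_mean, slope_pre_sd)),
            delta_slope=float(rng.normal(delta_slope_mean, delta_slope_sd)),
            breakpoint=breakpoint,
            event_spread=event_spread,
            residual_sd=residual_sd,
        )
    return norms


@dataclass
class RegressionSet:
    """A single simulated (x, x2, y) series plus its generating parameters."""

    x: np.ndarray
    x2: np.ndarray | None
    y: np.ndarray
    truth: dict = field(default_factory=dict)


def generate_regression_set(
    n: int,
    norm: ReactionNorm,
    cue_mean: float = 160.0,
    cue_sd: float = 8.0,
    seed=None,
    x: np.ndarray | None = None,
    with_covariate: bool = False,
    covariate_sd: float = 1.0,
) -> RegressionSet:
    """Draw one series straight from the piecewise-linear model.

    ``x`` may be supplied directly (e.g. to pin the breakpoint to an observed
    value); otherwise cues are Gaussian.  The returned truth dictionary
    expresses the generating parameters in the regression parametrisation
    (beta0 at x = 0, beta1, beta2, k).
    """
    if n < 8:
        raise ValueError("n must be >= 8")
    rng = as_generator(seed)
    if x is None:
        x = rng.normal(cue_mean, cue_sd, n)
    else:
        x = np.asarray(x, dtype=float)
        if x.size != n:
            raise ValueError("supplied x must have length n")
    x2 = rng.normal(0.0, covariate_sd, n) if with_covariate else None
    y = norm.event_day(x, x2 if x2 is not None else 0.0)
    y = y + rng.normal(0.0, norm.residual_sd, n)
    truth = {
        "beta0": norm.baseline_event_day - norm.slope_pre * norm.breakpoint,
        "beta1": norm.slope_pre,
        "beta2": norm.delta_slope,
        "k": norm.breakpoint,
        "gamma": norm.covariate_slope if with_covariate else None,
        "sigma": norm.residual_sd,
    }
    return RegressionSet(x=x, x2=x2, y=y, truth=truth)
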