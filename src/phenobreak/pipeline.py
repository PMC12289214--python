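"""End-to-end pipeline: simulate -> phenometrics -> climate -> breakpoint -> meta.

The pipeline reproduces the full inferential chain on either synthetic data
(from :mod:`phenobreak.simulate`) or user-supplied CSV tables with the same
schemas.  Four model variants are fitted per phenological event: snowmelt
only, temperature only, snowmelt with temperature as a linear covariate, and
temperature with snowmelt as a covariate — with the breakpoint always on the
first-named cue.  The per-series breakpoint fits (with null-calibrated SEs
and p-values) feed the multilevel meta-regression, yielding a summary table
of pooled slope-1 and delta-slope estimates per model and event.

All stages are deterministic for a fixed config seed: per-series calibration
streams are derived by hashing the series labels, so results do not depend
on iteration order.  Excluded series are logged with their reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as clim
from . import breakpoint as bp
from ._rng import series_stream
from .meta import fit_meta
from .phenometrics import (
    FitError,
    apply_inclusion_filters,
    extract_events,
    fit_seasonal_curve,
)
from .simulate import ClimateScenario, ReactionNorm, TrapDesign, generate_climate, generate_counts

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "MODEL_VARIANTS"]

log = logging.getLogger("phenobreak.pipeline")


def read_csv(path, **kw):
    """read_csv with exact float round-tripping (pipeline intermediates are
    written at full precision and must re-load bit-identically)."""
    return pd.read_csv(path, float_precision="round_trip", **kw)

#: (label, breakpoint cue, covariate cue or None)
MODEL_VARIANTS = (
    ("snowmelt", "snowmelt", None),
    ("temperature", "temperature", None),
    ("snowmelt + temperature", "snowmelt", "temperature"),
    ("temperature + snowmelt", "temperature", "snowmelt"),
)

EVENTS = ("onset", "peak", "end")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (one input mode: synthetic xor files)."""

    seed: int
    output_dir: Path
    synthetic: dict | None = None  # scenario/design/taxa blocks
    files: dict | None = None  # counts/air/snow/soil CSV paths
    events: tuple = EVENTS
    n_null: int = 200
    min_segment: int = 3
    min_years_per_series: int = 8
    min_total_per_year: int = 50
    min_intervals_present: int = 2
    basis_dim: int = 4
    models: tuple = MODEL_VARIANTS
    random_terms: tuple = ("taxon", "plot", "taxon:plot")

    def __post_init__(self):
        if (self.synthetic is None) == (self.files is None):
            raise ValueError("config must provide exactly one of 'synthetic' or 'files'")
        if self.n_null < 1 or self.min_segment < 2 or self.basis_dim < 3:
            raise ValueError("n_null, min_segment and basis_dim must be positive/sane")
        if self.min_total_per_year < 0 or self.min_intervals_present < 1:
            raise ValueError("filter thresholds must be positive")
        bad = set(self.events) - set(EVENTS)
        if bad:
            raise ValueError(f"unknown events: {sorted(bad)}")
        self.output_dir = Path(self.output_dir)


def load_config(path, seed_override=None, outdir_override=None) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError(f"{path}: config must set an explicit seed")
    if seed_override is not None:
        raw["seed"] = seed_override
    if outdir_override is not None:
        raw["output_dir"] = outdir_override
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("events", "models", "random_terms"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(tuple(m) if isinstance(m, list) else m for m in raw[key])
    return PipelineConfig(**raw)


def _build_synthetic(cfg: PipelineConfig):
    block = cfg.synthetic
    scenario = ClimateScenario(seed=cfg.seed, **block.get("scenario", {}))
    design = TrapDesign(**block.get("design", {}))
    taxa = block.get("taxa")
    if not taxa:
        raise ValueError("synthetic config must define at least one taxon")
    norms = {name: ReactionNorm(**(params or {})) for name, params in taxa.items()}
    climate = generate_climate(scenario)
    counts, truth = generate_counts(climate, norms, design, seed=cfg.seed + 1)
    return climate, counts, truth


def _load_files(cfg: PipelineConfig):
    from .simulate import ClimateData

    f = cfg.files
    required = {"counts", "air", "snow", "soil"}
    missing = required - set(f)
    if missing:
        raise ValueError(f"files config missing entries: {sorted(missing)}")
    counts = read_csv(f["counts"])
    need = {"taxon", "plot", "year", "interval_start_doy", "interval_end_doy", "trap_id", "count"}
    lacking = need - set(counts.columns)
    if lacking:
        raise ValueError(f"{f['counts']}: missing columns {sorted(lacking)}")
    climate = ClimateData(
        air=read_csv(f["air"]),
        snow=read_csv(f["snow"]),
        soil=read_csv(f["soil"]),
        snowmelt_true={},
    )
    return climate, counts, None


def _phenology_stage(cfg: PipelineConfig, counts: pd.DataFrame):
    """Fit every taxon x plot x year curve, extract events, apply filters."""
    events, failures = [], []
    for (taxon, plot, year), slc in counts.groupby(["taxon", "plot", "year"]):
        try:
            fit = fit_seasonal_curve(slc, basis_dim=cfg.basis_dim)
            events.append(extract_events(fit))
        except FitError as exc:
            failures.append({"taxon": taxon, "plot": plot, "year": year, "reason": str(exc)})
    apply_inclusion_filters(
        events,
        counts,
        min_total_per_year=cfg.min_total_per_year,
        min_intervals_present=cfg.min_intervals_present,
    )
    for ev in events:
        if ev.qc_flags:
            failures.append(
                {"taxon": ev.taxon, "plot": ev.plot, "year": ev.year,
                 "reason": "qc:" + ";".join(sorted(ev.qc_flags))}
            )
    rows = [
        {"taxon": e.taxon, "plot": e.plot, "year": e.year, "onset": e.onset_day,
         "peak": e.peak_day, "end": e.end_day, "flags": ";".join(sorted(e.qc_flags))}
        for e in events
    ]
    return pd.DataFrame(rows), pd.DataFrame(failures, columns=["taxon", "plot", "year", "reason"])


def _climate_stage(cfg: PipelineConfig, climate, events_df: pd.DataFrame):
    """Snowmelt per year (depth sensor, zero-curtain fallback) and the
    30-day temperature predictor per retained series and event."""
    years = sorted(set(climate.snow.year))
    snowmelt = {}
    for year in years:
        snowmelt[year] = clim.snowmelt_with_fallback(
            climate.snow[climate.snow.year == year],
            climate.soil[climate.soil.year == year],
        )
    retained = events_df[events_df["flags"] == ""]
    temp_rows = []
    for (taxon, plot), grp in retained.groupby(["taxon", "plot"]):
        for event in cfg.events:
            days = dict(zip(grp.year, grp[event]))
            if len(days) < 3:
                continue
            tw = clim.temperature_window(days, climate.air)
            tw["taxon"], tw["plot"], tw["event"] = taxon, plot, event
            temp_rows.append(tw)
    temp = (
        pd.concat(temp_rows, ignore_index=True)
        if temp_rows
        else pd.DataFrame(columns=["year", "temp_window_mean", "window_start_day",
                                   "window_end_day", "taxon", "plot", "event"])
    )
    snow_df = pd.DataFrame({"year": years, "snowmelt_day": [snowmelt[y] for y in years]})
    return snow_df, temp


def _breakpoint_stage(cfg: PipelineConfig, events_df, snow_df, temp_df):
    """Per-series linear + breakpoint fits with null-calibrated inference."""
    retained = events_df[events_df["flags"] == ""]
    rows, skipped = [], []
    for (taxon, plot), grp in retained.groupby(["taxon", "plot"]):
        for event in cfg.events:
            series = grp[["year", event]].merge(snow_df, on="year")
            tsub = temp_df[
                (temp_df["taxon"] == taxon)
                & (temp_df["plot"] == plot)
                & (temp_df["event"] == event)
            ][["year", "temp_window_mean"]]
            series = series.merge(tsub, on="year", how="left")
            n = len(series)
            if n < cfg.min_years_per_series:
                skipped.append({"taxon": taxon, "plot": plot, "event": event,
                                "reason": f"only {n} retained years"})
                continue
            cues = {"snowmelt": series.snowmelt_day.to_numpy(),
                    "temperature": series.temp_window_mean.to_numpy()}
            y = series[event].to_numpy(dtype=float)
            for label, main, covar in cfg.models:
                x = cues[main]
                x2 = cues[covar] if covar else None
                if np.any(~np.isfinite(x)) or (x2 is not None and np.any(~np.isfinite(x2))):
                    skipped.append({"taxon": taxon, "plot": plot, "event": event,
                                    "reason": f"{label}: missing predictor values"})
                    continue
                try:
                    lin = bp.fit_linear(x, y, x2)
                    fit = bp.fit_breakpoint(x, y, x2, min_segment=cfg.min_segment)
                    cal = bp.null_calibration(
                        x, y, x2, n_null=cfg.n_null,
                        seed=series_stream(cfg.seed, taxon, plot, event, label),
                        min_segment=cfg.min_segment,
                    )
                except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
                    skipped.append({"taxon": taxon, "plot": plot, "event": event,
                                    "reason": f"{label}: {exc}"})
                    continue
                rows.append({
                    "taxon": taxon, "plot": plot, "event": event, "model": label,
                    "predictor": main,
                    "beta0": fit.beta0, "beta1": fit.beta1, "se_beta1": cal.se_beta1,
                    "beta2": fit.beta2, "se_beta2": cal.se_beta2, "k": fit.k,
                    "gamma": fit.gamma if fit.gamma is not None else np.nan,
                    "p_delta": cal.p_delta,
                    "r2_linear": lin.r2, "r2_breakpoint": fit.r2, "n": fit.n,
                })
    cols = ["taxon", "plot", "event", "model", "predictor", "beta0", "beta1",
            "se_beta1", "beta2", "se_beta2", "k", "gamma", "p_delta",
            "r2_linear", "r2_breakpoint", "n"]
    return (pd.DataFrame(rows, columns=cols),
            pd.DataFrame(skipped, columns=["taxon", "plot", "event", "reason"]))


def _meta_stage(cfg: PipelineConfig, series_df: pd.DataFrame):
    """Pool slope-1 and delta-slope estimates per model variant and event."""
    rows = []
    for label, main, _ in cfg.models:
        for event in cfg.events:
            sub = series_df[(series_df.model == label) & (series_df.event == event)]
            sub = sub[(sub.se_beta1 > 0) & (sub.se_beta2 > 0)]
            if len(sub) < 2:
                log.warning("meta: %s / %s has %d usable series; skipped", label, event, len(sub))
                continue
            row = {"model": label, "predictor": main, "event": event, "n_series": len(sub)}
            for kind, est_col, se_col in (
                ("slope1", "beta1", "se_beta1"),
                ("delta_slope", "beta2", "se_beta2"),
            ):
                records = pd.DataFrame({
                    "estimate": sub[est_col].to_numpy(),
                    "variance": sub[se_col].to_numpy() ** 2,
                    "taxon": sub["taxon"].to_numpy(),
                    "plot": sub["plot"].to_numpy(),
                })
                res = fit_meta(records, random_terms=cfg.random_terms)
                row.update({
                    f"{kind}_est": res.estimate, f"{kind}_se": res.se,
                    f"{kind}_ci_low": res.ci_low, f"{kind}_ci_high": res.ci_high,
                    f"{kind}_q": res.q_stat, f"{kind}_q_p": res.q_pvalue,
                })
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, write_outputs: bool = True) -> dict:
    """Run the full chain and write all tables under ``cfg.output_dir``.

    Returns the intermediate and final tables keyed by stage.  Raises (with
    no partial outputs) if the count table is empty or malformed.  With
    ``write_outputs=False`` nothing touches disk (useful when the pipeline
    is replicated inside a simulation loop).
    """
    if cfg.synthetic is not None:
        climate, counts, truth = _build_synthetic(cfg)
    else:
        climate, counts, truth = _load_files(cfg)
    if counts.empty:
        raise ValueError("count table is empty; nothing to analyse")

    events_df, failures = _phenology_stage(cfg, counts)
    if events_df.empty:
        raise ValueError("no seasonal curves could be fitted")
    snow_df, temp_df = _climate_stage(cfg, climate, events_df)
    series_df, skipped = _breakpoint_stage(cfg, events_df, snow_df, temp_df)
    meta_df = _meta_stage(cfg, series_df)

    if write_outputs:
        out = cfg.output_dir
        out.mkdir(parents=True, exist_ok=True)
        counts.to_csv(out / "counts.csv", index=False, float_format="%.17g")
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False, float_format="%.17g")
        climate.write_csv(out / "climate")
        events_df.to_csv(out / "events.csv", index=False, float_format="%.17g")
        failures.to_csv(out / "excluded_series.csv", index=False, float_format="%.17g")
        snow_df.to_csv(out / "snowmelt.csv", index=False, float_format="%.17g")
        temp_df.to_csv(out / "temperature_windows.csv", index=False, float_format="%.17g")
        series_df.to_csv(out / "series_results.csv", index=False, float_format="%.17g")
        skipped.to_csv(out / "skipped_series.csv", index=False, float_format="%.17g")
        meta_df.to_csv(out / "meta_results.csv", index=False, float_format="%.17g")
    log.info(
        "pipeline complete: %d series fits, %d meta rows, %d exclusions, %d skips",
        len(series_df), len(meta_df), len(failures), len(skipped),
    )
    return {
        "counts": counts, "truth": truth, "events": events_df,
        "excluded": failures, "snowmelt": snow_df, "temperature": temp_df,
        "series": series_df, "skipped": skipped, "meta": meta_df,
    }
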