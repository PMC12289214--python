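"""Climate predictors: snowmelt date, pre-season temperature, collinearity.

Two snowmelt estimators are provided.  The primary one reads the station
snow-depth series and returns the (interpolated) day the depth drops below
10 cm for good, i.e. without re-crossing before season end — a transient
one-day dip is not melt-out.  In low-snow years where the depth sensor never
registers 10 cm the soil-temperature fallback is used instead: the end of
the "zero-curtain", the late-winter plateau during which latent heat pins
the depth-averaged soil temperature near 0 deg C; melt-out is the first day
afterwards on which the within-day range starts fluctuating.

The temperature predictor for an event series is the mean air temperature
over a fixed 30-day day-of-year window shared across years, anchored at the
across-year mean event date minus one across-year SD (capturing conditions
during the pre-emergence development window while avoiding circularity of a
year-specific anchor).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LowSnowError",
    "snowmelt_from_depth",
    "snowmelt_zero_curtain",
    "snowmelt_with_fallback",
    "temperature_window",
    "vif",
]

SNOW_THRESHOLD_CM = 10.0
PLATEAU_MEAN_TOL = 0.5  # deg C; |depth-averaged mean| during the plateau
PLATEAU_RANGE_TOL = 0.5  # deg C; within-day range during the plateau
FLUCTUATION_TRIGGER = 1.0  # deg C; range that marks bare ground
LATE_WINTER_END_DOY = 250  # plateau runs must end before mid-season
WINDOW_DAYS = 30


class LowSnowError(ValueError):
    """Snow depth never reached the threshold; use the zero-curtain fallback."""


def snowmelt_from_depth(
    snow: pd.DataFrame,
    threshold_cm: float = SNOW_THRESHOLD_CM,
    season_end_doy: int = LATE_WINTER_END_DOY,
) -> float:
    """Day-of-year the snow depth drops below ``threshold_cm`` and stays there.

    ``snow`` holds one year: columns ``doy`` and ``depth_cm``.  The crossing
    day is linearly interpolated between the last daily reading at or above
    the threshold and the first below it.  Only the melt season (doy <=
    ``season_end_doy``) is considered, so autumn re-accumulation is ignored.
    """
    s = snow[snow.doy <= season_end_doy].sort_values("doy")
    if s.empty:
        raise ValueError("snow series does not cover the melt season")
    doy = s.doy.to_numpy(dtype=float)
    depth = s.depth_cm.to_numpy(dtype=float)
    below = depth < threshold_cm
    if below.all():
        raise LowSnowError(
            "snow depth below threshold all season; use snowmelt_zero_curtain"
        )
    if not below.any() or not below[-1]:
        raise ValueError("snow depth never dropped below the threshold for good")
    # last index at/above threshold after which depth stays below (sustained)
    i = int(np.max(np.flatnonzero(~below)))
    d0, d1 = depth[i], depth[i + 1]
    t0, t1 = doy[i], doy[i + 1]
    return float(t0 + (d0 - threshold_cm) / (d0 - d1) * (t1 - t0))


def snowmelt_zero_curtain(
    soil: pd.DataFrame,
    mean_tol: float = PLATEAU_MEAN_TOL,
    range_tol: float = PLATEAU_RANGE_TOL,
    trigger: float = FLUCTUATION_TRIGGER,
    late_winter_end_doy: int = LATE_WINTER_END_DOY,
) -> float:
    """Melt-out day from the end of the soil zero-curtain plateau.

    ``soil`` holds one year at depths 0/5/10 cm: columns ``doy``,
    ``depth_cm``, ``t_mean``, ``t_range``.  The series are averaged across
    depths; the longest run of days before ``late_winter_end_doy`` with
    |mean| <= ``mean_tol`` and range <= ``range_tol`` is the zero-curtain,
    and the first subsequent day whose within-day range exceeds ``trigger``
    is returned.
    """
    avg = soil.groupby("doy")[["t_mean", "t_range"]].mean().sort_index()
    doy = avg.index.to_numpy(dtype=float)
    in_plateau = (
        (np.abs(avg.t_mean.to_numpy()) <= mean_tol)
        & (avg.t_range.to_numpy() <= range_tol)
        & (doy <= late_winter_end_doy)
    )
    if not in_plateau.any():
        raise ValueError("no zero-curtain plateau found")
    # longest run of consecutive plateau days
    best_len, best_end, run = 0, -1, 0
    for i, flag in enumerate(in_plateau):
        run = run + 1 if flag else 0
        if run >= best_len:  # >= keeps the latest equally long run
            best_len, best_end = run, i
    if best_len < 5:
        raise ValueError("no sustained zero-curtain plateau found")
    after = avg.t_range.to_numpy()[best_end + 1 :]
    idx = np.flatnonzero(after > trigger)
    if idx.size == 0:
        raise ValueError("soil never starts fluctuating after the plateau")
    return float(doy[best_end + 1 + idx[0]])


def snowmelt_with_fallback(snow_year: pd.DataFrame, soil_year: pd.DataFrame) -> float:
    """Depth-based estimate, falling back to the zero-curtain in low-snow years."""
    try:
        return snowmelt_from_depth(snow_year)
    except LowSnowError:
        return snowmelt_zero_curtain(soil_year)


def temperature_window(
    event_days: dict,
    air: pd.DataFrame,
    window_days: int = WINDOW_DAYS,
) -> pd.DataFrame:
    """Pre-season temperature predictor for one event series.

    ``event_days`` maps year -> event day-of-year (>= 3 years so the SD is
    meaningful); ``air`` has columns ``year``, ``doy``, ``t_mean``.  The
    anchor is round(mean - SD) of the event days across years; the window is
    the ``window_days`` days [anchor - window_days, anchor), identical in
    every year.  Returns one row per year with the window mean.
    """
    if len(event_days) < 3:
        raise ValueError("need at least 3 years of events to anchor the window")
    days = np.array(list(event_days.values()), dtype=float)
    anchor = int(round(days.mean() - days.std(ddof=1)))
    start = anchor - window_days
    sub = air[(air.doy >= start) & (air.doy < anchor)]
    stats_by_year = sub.groupby("year")["t_mean"].agg(["mean", "size", "min"])
    mins = sub.groupby("year")["doy"].min()
    rows = []
    for year in sorted(event_days):
        if (
            year not in stats_by_year.index
            or stats_by_year.loc[year, "size"] < window_days
            or mins.loc[year] != start
        ):
            raise ValueError(
                f"temperature window [{start}, {anchor}) not fully covered in {year}"
            )
        rows.append(
            {
                "year": year,
                "temp_window_mean": float(stats_by_year.loc[year, "mean"]),
                "window_start_day": start,
                "window_end_day": anchor,
            }
        )
    return pd.DataFrame(rows)


def vif(X) -> np.ndarray:
    """Variance inflation factor of each column of ``X``.

    VIF_j = 1 / (1 - R^2_j) from an OLS regression (with intercept) of
    column j on the remaining columns; perfect collinearity gives inf.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 predictor columns")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more observations than predictors plus one")
    out = np.empty(p)
    for j in range(p):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out
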