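"""Seasonal activity curves and onset/peak/end phenometrics.

For each taxon x plot x year, the catch per trap per day is modelled as a
Poisson GAM of day-of-year: a log-link Poisson regression on a cubic
regression spline basis with 4 basis functions (enough flexibility for a
single seasonal pulse without chasing sampling noise).  Counts are totalled
per emptying interval and fitted with a log(trap-days) exposure, which is the
count-level equivalent of smoothing the per-trap-per-day abundance assigned
to interval midpoints.

Onset, peak and end of activity are the days on which the cumulative area
under the fitted curve reaches 10%, 50% and 90% of its season total.
Series are screened by the inclusion rules used for Arctic trap data:
a minimum of 50 individuals of the taxon per year across plots, presence in
at least two emptying intervals, and a plausible unimodal, roughly symmetric
seasonal curve (multimodal or strongly asymmetric fits are flagged and
excluded, as are curves truncated by the start or end of trapping).
"""

from __future__ import annotations

import typing as t
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator

__all__ = [
    "SeasonalFit",
    "PhenoEvent",
    "SeasonalActivityModel",
    "FitError",
    "fit_seasonal_curve",
    "extract_events",
    "apply_inclusion_filters",
    "events_to_frame",
]

GRID_STEP = 0.1  # days; trapezoid integration grid
QUANTILES = (0.10, 0.50, 0.90)
#: boundary density above this fraction of the maximum marks a truncated curve
TRUNCATION_BOUNDARY_FRAC = 0.5
#: interior local maxima below this fraction of the global maximum are ignored
MODE_HEIGHT_FRAC = 0.05


class FitError(RuntimeError):
    """Seasonal curve could not be fitted (degenerate or non-converging)."""


@dataclass
class SeasonalFit:
    """Fitted daily activity curve for one taxon x plot x year."""

    taxon: str
    plot: str
    year: int
    grid: np.ndarray  # day-of-year, fine step
    fitted: np.ndarray  # expected catch per trap per day, >= 0
    basis_dim: int
    total_catch: int
    n_intervals_present: int  # intervals with at least one individual
    deviance: float


@dataclass
class PhenoEvent:
    """Onset/peak/end (10/50/90% cumulative activity) with QC diagnostics."""

    taxon: str
    plot: str
    year: int
    onset_day: float
    peak_day: float
    end_day: float
    qc_flags: set = field(default_factory=set)
    n_interior_maxima: int = 1
    has_interior_dip: bool = False
    boundary_frac: float = 0.0
    total_catch: int = 0
    n_intervals_present: int = 0

    @property
    def asymmetry(self) -> float:
        """(peak - onset) / (end - peak); 1 for a symmetric curve."""
        denom = self.end_day - self.peak_day
        return np.inf if denom <= 0 else (self.peak_day - self.onset_day) / denom


class _Intervals(t.NamedTuple):
    """Per-interval totals for one series (sorted by midpoint)."""

    start: np.ndarray
    end: np.ndarray
    total: np.ndarray
    n_traps: np.ndarray
    midpoint: np.ndarray
    trap_days: np.ndarray


def _aggregate_intervals(counts: pd.DataFrame) -> _Intervals:
    # numpy aggregation: this runs thousands of times per pipeline pass
    start = counts["interval_start_doy"].to_numpy(dtype=float)
    end = counts["interval_end_doy"].to_numpy(dtype=float)
    cnt = counts["count"].to_numpy(dtype=float)
    trap_codes = pd.factorize(counts["trap_id"])[0]
    keys, inv = np.unique(np.column_stack([start, end]), axis=0, return_inverse=True)
    totals = np.bincount(inv, weights=cnt, minlength=len(keys))
    pair = np.unique(np.column_stack([inv, trap_codes]), axis=0)
    n_traps = np.bincount(pair[:, 0], minlength=len(keys))
    s, e = keys[:, 0], keys[:, 1]  # np.unique sorts, so midpoints are ordered
    return _Intervals(
        start=s,
        end=e,
        total=totals,
        n_traps=n_traps,
        midpoint=0.5 * (s + e),
        trap_days=(e - s) * n_traps,
    )


@lru_cache(maxsize=512)
def _cardinal_spline(knots: tuple) -> CubicSpline:
    # interval layouts repeat across series, so cache the basis constructor
    k = np.asarray(knots, dtype=float)
    return CubicSpline(k, np.eye(k.size), bc_type="natural", axis=0)


@lru_cache(maxsize=512)
def _grid_and_basis(knots: tuple, lo: float, hi: float):
    grid = np.arange(lo, hi + GRID_STEP / 2, GRID_STEP)
    B = cr_basis(grid, np.asarray(knots))
    grid.setflags(write=False)
    B.setflags(write=False)
    return grid, B


def cr_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Cardinal natural-cubic-spline basis evaluated at ``x``.

    Column j is the natural cubic spline that is 1 at ``knots[j]`` and 0 at
    the other knots, extended linearly beyond the boundary knots.  The
    columns sum to one at every x, so the basis spans constants and needs no
    separate intercept.
    """
    knots = np.asarray(knots, dtype=float)
    cs = _cardinal_spline(tuple(knots))
    lo, hi = knots[0], knots[-1]
    x = np.asarray(x, dtype=float)
    B = cs(np.clip(x, lo, hi))
    below, above = x < lo, x > hi
    if below.any():
        B[below] += np.outer(x[below] - lo, cs(lo, 1))
    if above.any():
        B[above] += np.outer(x[above] - hi, cs(hi, 1))
    return B


def _poisson_irls(X, y, offset, maxiter: int = 100, tol: float = 1e-10):
    """Poisson log-link ML fit by iteratively reweighted least squares.

    Lean Newton scoring for the small fixed-basis fits done thousands of
    times per pipeline pass; agreement with a reference GLM implementation
    is pinned by a unit test.  Returns (beta, deviance).
    """
    n, p = X.shape
    # basis rows sum to one, so a constant eta is X @ (c * ones)
    mu0 = max(float(np.sum(y) / np.sum(np.exp(offset))), 1e-8)
    beta = np.full(p, np.log(mu0))
    dev_old = np.inf
    for _ in range(maxiter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * mu
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular weighted normal equations: {exc}") from exc
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        dev = 2.0 * float(np.sum(term - (y - mu)))
        if not np.isfinite(dev):
            raise FitError("Poisson spline fit diverged")
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            return beta, dev
        dev_old = dev
    raise FitError("Poisson spline fit did not converge")


def fit_seasonal_curve(counts: pd.DataFrame, basis_dim: int = 4) -> SeasonalFit:
    """Fit the Poisson spline curve to one taxon x plot x year slice.

    ``counts`` needs columns interval_start_doy, interval_end_doy, trap_id,
    count (taxon/plot/year columns are carried through if present).  Interval
    totals are modelled with a log(trap-days) exposure, so the fitted curve
    is on the per-trap-per-day scale.
    """
    if counts.empty:
        raise FitError("empty count slice")
    agg = _aggregate_intervals(counts)
    n_int = agg.midpoint.size
    if n_int < 3:
        raise FitError("need at least 3 distinct emptying intervals")
    if agg.total.sum() == 0:
        raise FitError("all counts are zero")
    if n_int < basis_dim:
        raise FitError(
            f"{n_int} intervals cannot support a {basis_dim}-function basis"
        )
    x = agg.midpoint
    y = agg.total
    # knots at equally spaced quantiles of the interval midpoints; the
    # cardinal basis spans constants, so no separate intercept is added
    knots = np.quantile(np.unique(x), np.linspace(0.0, 1.0, basis_dim))
    if np.unique(knots).size < basis_dim:
        raise FitError("interval midpoints too clustered to place distinct knots")
    X = cr_basis(x, knots)
    offset = np.log(agg.trap_days)
    beta, deviance = _poisson_irls(X, y, offset)

    lo = float(agg.start.min())
    hi = float(agg.end.max())
    grid, B = _grid_and_basis(tuple(knots), lo, hi)
    fitted = np.exp(np.clip(B @ beta, -30.0, 30.0))

    def _first(col, default):
        return counts[col].iloc[0] if col in counts.columns else default

    return SeasonalFit(
        taxon=_first("taxon", "?"),
        plot=_first("plot", "?"),
        year=int(_first("year", 0)),
        grid=grid,
        fitted=fitted,
        basis_dim=basis_dim,
        total_catch=int(agg.total.sum()),
        n_intervals_present=int((agg.total > 0).sum()),
        deviance=float(deviance),
    )


def _interior_maxima(fitted: np.ndarray) -> int:
    """Count interior local maxima taller than MODE_HEIGHT_FRAC of the peak."""
    f = fitted
    thresh = MODE_HEIGHT_FRAC * f.max()
    d = np.diff(f)
    rising = d > 0
    # a maximum is a switch from rising to non-rising
    switches = np.flatnonzero(rising[:-1] & ~rising[1:]) + 1
    return int(np.sum(f[switches] > thresh))


def _has_interior_dip(fitted: np.ndarray) -> bool:
    """Interior local minimum with a >5%-of-peak rise on both sides.

    A stiff low-dimension spline fitted to two separated activity pulses
    often renders them as a U- or W-shape rather than two clean interior
    maxima; the dip is the robust signature of a non-unimodal season.
    """
    f = fitted
    rise = MODE_HEIGHT_FRAC * f.max()
    d = np.diff(f)
    falling = d < 0
    valleys = np.flatnonzero(falling[:-1] & ~falling[1:]) + 1
    for v in valleys:
        if f[: v + 1].max() - f[v] > rise and f[v:].max() - f[v] > rise:
            return True
    return False


def extract_events(fit: SeasonalFit) -> PhenoEvent:
    """Onset/peak/end from the cumulative area under the fitted curve.

    The cumulative integral is a trapezoid sum on the fine grid; each event
    day is found by linear interpolation of the cumulative fraction at its
    threshold.  Diagnostics for the inclusion filters (interior mode count,
    relative boundary density) are computed here; flags are assigned by
    :func:`apply_inclusion_filters`.
    """
    cum = cumulative_trapezoid(fit.fitted, fit.grid, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise FitError("fitted curve integrates to zero")
    frac = cum / total
    days = [float(np.interp(q, frac, fit.grid)) for q in QUANTILES]
    boundary_frac = float(max(fit.fitted[0], fit.fitted[-1]) / fit.fitted.max())
    return PhenoEvent(
        taxon=fit.taxon,
        plot=fit.plot,
        year=fit.year,
        onset_day=days[0],
        peak_day=days[1],
        end_day=days[2],
        n_interior_maxima=_interior_maxima(fit.fitted),
        has_interior_dip=_has_interior_dip(fit.fitted),
        boundary_frac=boundary_frac,
        total_catch=fit.total_catch,
        n_intervals_present=fit.n_intervals_present,
    )


def apply_inclusion_filters(
    events: list,
    counts: pd.DataFrame | None = None,
    min_total_per_year: int = 50,
    min_intervals_present: int = 2,
    asymmetry_bounds: tuple = (1.0 / 3.0, 3.0),
    truncation_boundary_frac: float = TRUNCATION_BOUNDARY_FRAC,
) -> list:
    """Assign QC flags; an event is retained only if its flag set is empty.

    Flags
    -----
    low_abundance
        fewer than ``min_total_per_year`` individuals of the taxon caught in
        that year summed across all plots (``counts`` supplies the cross-plot
        totals; without it the per-series total is used);
    short_presence
        individuals present in fewer than ``min_intervals_present`` emptying
        intervals;
    multimodal
        the fitted curve has more than one interior local maximum, or an
        interior dip (local minimum with a substantial rise on both sides —
        how a stiff spline renders two separated pulses);
    asymmetric
        (peak - onset)/(end - peak) outside ``asymmetry_bounds`` — a numeric
        stand-in for the qualitative "plausible seasonal curve" screen;
    truncated
        fitted density at the first or last trapping day exceeds
        ``truncation_boundary_frac`` of the curve maximum (the season began
        or ended during peak activity).
    """
    if counts is not None and len(counts):
        year_totals = counts.groupby(["taxon", "year"])["count"].sum().to_dict()
    else:
        year_totals = None
    lo, hi = asymmetry_bounds
    for ev in events:
        ev.qc_flags = set()
        total = (
            year_totals.get((ev.taxon, ev.year), 0)
            if year_totals is not None
            else ev.total_catch
        )
        if total < min_total_per_year:
            ev.qc_flags.add("low_abundance")
        if ev.n_intervals_present < min_intervals_present:
            ev.qc_flags.add("short_presence")
        if ev.n_interior_maxima > 1 or ev.has_interior_dip:
            ev.qc_flags.add("multimodal")
        ratio = ev.asymmetry
        if not (lo <= ratio <= hi):
            ev.qc_flags.add("asymmetric")
        if ev.boundary_frac > truncation_boundary_frac:
            ev.qc_flags.add("truncated")
    return events


def events_to_frame(events: list, retained_only: bool = True) -> pd.DataFrame:
    rows = []
    for ev in events:
        if retained_only and ev.qc_flags:
            continue
        rows.append(
            {
                "taxon": ev.taxon,
                "plot": ev.plot,
                "year": ev.year,
                "onset": ev.onset_day,
                "peak": ev.peak_day,
                "end": ev.end_day,
                "flags": ";".join(sorted(ev.qc_flags)),
                "total_catch": ev.total_catch,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["taxon", "plot", "year", "onset", "peak", "end", "flags", "total_catch"],
    )


class SeasonalActivityModel(BaseEstimator):
    """Estimator wrapper: fit one seasonal curve and expose its phenometrics.

    Parameters
    ----------
    basis_dim : int, default 4
        Number of cubic-regression-spline basis functions.

    Attributes
    ----------
    fit_ : SeasonalFit
    curve_grid_, curve_ : ndarray
        Day grid and fitted per-trap-per-day abundance.
    event_ : PhenoEvent
        Onset/peak/end with QC diagnostics (flags not yet assigned).
    """

    def __init__(self, basis_dim: int = 4):
        self.basis_dim = basis_dim

    def fit(self, counts: pd.DataFrame, y=None):
        self.fit_ = fit_seasonal_curve(counts, basis_dim=self.basis_dim)
        self.curve_grid_ = self.fit_.grid
        self.curve_ = self.fit_.fitted
        self.event_ = extract_events(self.fit_)
        return self

    def transform(self, counts: pd.DataFrame = None) -> pd.DataFrame:
        """Return the extracted events as a one-row data frame."""
        ev = self.event_
        return pd.DataFrame(
            [
                {
                    "taxon": ev.taxon,
                    "plot": ev.plot,
                    "year": ev.year,
                    "onset": ev.onset_day,
                    "peak": ev.peak_day,
                    "end": ev.end_day,
                }
            ]
        )
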