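"""Piecewise-linear ("breakpoint") phenology-climate regression.

The model for one taxon-by-plot time series relates an annual phenological
event day ``y`` to a climate cue ``x`` (snowmelt day-of-year or a pre-season
temperature) through a continuous two-segment line::

    y = b0 + b1 * x + b2 * (x - k) * 1[x >= k] + e,      e ~ N(0, sigma^2)

``b1`` is the slope of the first segment ("slope 1"), ``b2`` the *difference*
between second- and first-segment slopes ("delta slope"), and the breakpoint
``k`` is restricted to the observed cue values.  ``k`` is located by exhaustive
maximum-likelihood search.  An optional second cue enters linearly (only one
predictor carries a breakpoint at a time).

Because the breakpoint is itself estimated, the conditional least-squares
standard error of ``b2`` at the selected ``k`` ignores the model-selection
step and is badly anti-conservative.  Inference is therefore calibrated by a
parametric bootstrap under the no-breakpoint null: the observed log-likelihood
gain of the breakpoint model is referred to its null distribution, and the
standard errors of ``b1`` and ``b2`` are taken as the spread of their
estimates across null refits (:func:`null_calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._rng import as_generator

__all__ = [
    "LinearFit",
    "BreakpointFit",
    "CalibratedInference",
    "BreakpointRegression",
    "fit_linear",
    "fit_breakpoint",
    "null_calibration",
    "derive_second_segment_slope",
    "compare_r2",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class LinearFit:
    """Gaussian-ML straight-line fit (the no-breakpoint null model)."""

    beta0: float
    beta1: float
    gamma: float | None  # coefficient of the optional second cue
    sigma2: float  # ML residual variance, SSE / n
    loglik: float
    r2: float
    n: int
    sse: float


@dataclass(frozen=True)
class BreakpointFit:
    """ML fit of the two-segment model; ``k`` sits on an observed x value."""

    beta0: float
    beta1: float
    beta2: float
    k: float
    gamma: float | None
    sigma2: float
    loglik: float
    r2: float
    n: int
    sse: float

    @property
    def second_segment_slope(self) -> float:
        return self.beta1 + self.beta2


@dataclass(frozen=True)
class CalibratedInference:
    """Null-simulation calibration of the delta-slope test for one series."""

    p_delta: float
    se_beta1: float
    se_beta2: float
    n_null: int
    observed_llr: float
    n_failed: int


# ---------------------------------------------------------------------------
# numerics


def _gaussian_ml(X: np.ndarray, y: np.ndarray):
    """ML (= least squares) fit; returns (beta, sse).  Raises on rank defect."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _loglik_from_sse(sse: float, n: int) -> float:
    # Profile Gaussian log-likelihood at the MLE sigma2 = SSE / n.
    if sse <= 0.0:
        return np.inf  # perfect fit (noise-free data)
    return -0.5 * n * (_LOG2PI + np.log(sse / n) + 1.0)


def _hinge(x: np.ndarray, k: float) -> np.ndarray:
    return np.where(x >= k, x - k, 0.0)


def _design_linear(x, x2):
    cols = [np.ones_like(x), x]
    if x2 is not None:
        cols.append(x2)
    return np.column_stack(cols)


def _design_breakpoint(x, k, x2):
    cols = [np.ones_like(x), x, _hinge(x, k)]
    if x2 is not None:
        cols.append(x2)
    return np.column_stack(cols)


def _validate_xy(x, y, x2):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x2 is not None:
        x2 = np.asarray(x2, dtype=float).ravel()
        if x2.shape != x.shape:
            raise ValueError("x2 must match x in length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in x or y")
    return x, y, x2


def candidate_breakpoints(x: np.ndarray, min_segment: int = 3) -> np.ndarray:
    """Admissible breakpoints: observed x values leaving at least
    ``min_segment`` points strictly below and strictly above."""
    xs = np.unique(x)
    keep = [k for k in xs if (x < k).sum() >= min_segment and (x > k).sum() >= min_segment]
    return np.asarray(keep, dtype=float)


def fit_linear(x, y, x2=None) -> LinearFit:
    """Single-slope Gaussian-ML fit, the null model of the breakpoint test."""
    x, y, x2 = _validate_xy(x, y, x2)
    n = x.size
    p = 2 if x2 is None else 3
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} observations, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; slope is not identifiable")
    X = _design_linear(x, x2)
    beta, sse = _gaussian_ml(X, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    return LinearFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        gamma=float(beta[2]) if x2 is not None else None,
        sigma2=sse / n,
        loglik=_loglik_from_sse(sse, n),
        r2=r2,
        n=n,
        sse=sse,
    )


def fit_breakpoint(x, y, x2=None, min_segment: int = 3) -> BreakpointFit:
    """Exhaustive ML search for the breakpoint over observed x values.

    Every admissible ``k`` (>= ``min_segment`` points strictly on each side)
    is tried; for each, the piecewise model is fitted by least squares and the
    ``k`` with the smallest SSE (largest likelihood) wins.  Likelihood ties
    are broken toward the smallest ``k`` so results are deterministic.
    """
    x, y, x2 = _validate_xy(x, y, x2)
    n = x.size
    if n < 2 * min_segment:
        raise ValueError(f"need at least {2 * min_segment} observations, got {n}")
    cands = candidate_breakpoints(x, min_segment)
    if cands.size == 0:
        raise ValueError("too few distinct x values for any admissible breakpoint")
    best = None
    n_fail = 0
    for k in cands:  # ascending, so strict '<' keeps the smallest tied k
        X = _design_breakpoint(x, k, x2)
        try:
            beta, sse = _gaussian_ml(X, y)
        except np.linalg.LinAlgError:
            n_fail += 1
            continue
        if best is None or sse < best[1] - 1e-12 * max(1.0, best[1]):
            best = (beta, sse, k)
    if best is None:
        raise np.linalg.LinAlgError(
            f"all {n_fail} candidate breakpoint fits were rank-deficient"
        )
    beta, sse, k = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0.0 else 1.0 - sse / sst
    return BreakpointFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        k=float(k),
        gamma=float(beta[3]) if x2 is not None else None,
        sigma2=sse / n,
        loglik=_loglik_from_sse(sse, n),
        r2=r2,
        n=n,
        sse=sse,
    )


def _search_many(x, Y, x2=None, min_segment: int = 3):
    """Vectorised breakpoint search for many responses sharing one design.

    ``Y`` is (n, m): m response vectors on the same x (and x2).  Returns
    (sse, beta1, beta2, k) arrays of length m.  Used by the null calibration,
    where hundreds of simulated responses share the observed predictors; a
    unit test pins this path to :func:`fit_breakpoint` column by column.
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    cands = candidate_breakpoints(x, min_segment)
    if cands.size == 0:
        raise ValueError("too few distinct x values for any admissible breakpoint")
    yty = np.einsum("ij,ij->j", Y, Y)
    best_sse = np.full(m, np.inf)
    best_idx = np.full(m, -1)
    coefs = []  # per-candidate coefficient matrices (p, m)
    for ci, k in enumerate(cands):
        X = _design_breakpoint(x, k, x2)
        Q, R = np.linalg.qr(X)
        if np.min(np.abs(np.diag(R))) < 1e-10 * max(1.0, np.max(np.abs(R))):
            coefs.append(None)
            continue
        QtY = Q.T @ Y
        sse = np.maximum(yty - np.einsum("ij,ij->j", QtY, QtY), 0.0)
        coefs.append(np.linalg.solve(R, QtY))
        finite = np.isfinite(best_sse)
        thresh = np.full_like(best_sse, np.inf)
        thresh[finite] = best_sse[finite] - 1e-12 * np.maximum(1.0, best_sse[finite])
        better = sse < thresh
        best_sse[better] = sse[better]
        best_idx[better] = ci
    ok = best_idx >= 0
    beta1 = np.full(m, np.nan)
    beta2 = np.full(m, np.nan)
    kbest = np.full(m, np.nan)
    for ci in np.unique(best_idx[ok]):
        sel = best_idx == ci
        beta1[sel] = coefs[ci][1, sel]
        beta2[sel] = coefs[ci][2, sel]
        kbest[sel] = cands[ci]
    return best_sse, beta1, beta2, kbest, ok


def null_calibration(
    x,
    y,
    x2=None,
    n_null: int = 1000,
    seed=None,
    min_segment: int = 3,
    max_failure_frac: float = 0.05,
) -> CalibratedInference:
    """Parametric-bootstrap calibration of the delta-slope test.

    Fits the no-breakpoint null to ``(x, y)``, simulates ``n_null`` Gaussian
    response vectors from it (predictors held fixed, errors at the null's ML
    residual variance), refits both models to each, and compares the observed
    log-likelihood gain of the breakpoint model to its null distribution::

        p_delta = (1 + #{null LLR >= observed LLR}) / (n_valid + 1)

    The add-one convention keeps p strictly positive; it differs from the raw
    exceedance proportion by at most 1/(n_null + 1).  The standard errors of
    slope 1 and delta slope are the standard deviations of their estimates
    across the null refits, which absorb the breakpoint-search variability
    that conditional least-squares standard errors miss.
    """
    x, y, x2 = _validate_xy(x, y, x2)
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = as_generator(seed)
    lin = fit_linear(x, y, x2)
    bp = fit_breakpoint(x, y, x2, min_segment=min_segment)
    n = x.size
    sst = float(np.sum((y - y.mean()) ** 2))
    tol = 1e-12 * (sst + 1.0)
    if bp.sse < tol:
        # noise-free data: LLR is 0 if the linear model is also perfect,
        # otherwise unbounded
        observed_llr = 0.0 if lin.sse < tol else np.inf
    else:
        observed_llr = 0.5 * n * (np.log(lin.sse) - np.log(bp.sse))

    Xlin = _design_linear(x, x2)
    mu = Xlin @ np.array(
        [lin.beta0, lin.beta1] + ([] if x2 is None else [lin.gamma])
    )
    Y = mu[:, None] + np.sqrt(lin.sigma2) * rng.standard_normal((n, n_null))

    # Null linear refits (shared design): SSE via projection.
    Q, _ = np.linalg.qr(Xlin)
    QtY = Q.T @ Y
    sse_lin = np.maximum(np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", QtY, QtY), 0.0)
    sse_bp, b1, b2, _, ok = _search_many(x, Y, x2, min_segment=min_segment)

    valid = ok & np.isfinite(sse_lin) & (sse_bp > 0) & (sse_lin > 0)
    n_failed = int(n_null - valid.sum())
    if n_failed > max_failure_frac * n_null:
        raise RuntimeError(
            f"{n_failed}/{n_null} null refits failed; calibration unreliable"
        )
    llr = 0.5 * n * (np.log(sse_lin[valid]) - np.log(sse_bp[valid]))
    n_valid = int(valid.sum())
    if np.isinf(observed_llr):
        exceed = 0
    else:
        exceed = int(np.sum(llr >= observed_llr - 1e-12))
    p_delta = (1.0 + exceed) / (n_valid + 1.0)
    return CalibratedInference(
        p_delta=float(p_delta),
        se_beta1=float(np.std(b1[valid], ddof=1)),
        se_beta2=float(np.std(b2[valid], ddof=1)),
        n_null=n_valid,
        observed_llr=float(observed_llr),
        n_failed=n_failed,
    )


def naive_se_beta2(x, y, x2=None, min_segment: int = 3) -> float:
    """Conditional least-squares SE of the delta slope at the selected k.

    This is the textbook OLS standard error computed as if the breakpoint had
    been known in advance; it ignores the search over k and is the quantity
    the null-simulation SE corrects.
    """
    x, y, x2 = _validate_xy(x, y, x2)
    bp = fit_breakpoint(x, y, x2, min_segment=min_segment)
    X = _design_breakpoint(x, bp.k, x2)
    n, p = X.shape
    s2_unbiased = bp.sse / (n - p)
    cov = s2_unbiased * np.linalg.inv(X.T @ X)
    return float(np.sqrt(cov[2, 2]))


def derive_second_segment_slope(beta1: float, beta2: float) -> float:
    """Slope of the second segment: slope 1 plus the slope difference.

    A derived quantity with no standard error attached; the two inputs are
    correlated, so their SEs do not combine by simple propagation.
    """
    return beta1 + beta2


def compare_r2(linear: LinearFit, piecewise: BreakpointFit):
    """Paired in-sample R^2 of the nested linear and breakpoint fits."""
    if linear.n != piecewise.n:
        raise ValueError("fits are not on the same data")
    return linear.r2, piecewise.r2


# ---------------------------------------------------------------------------
# estimator interface


class BreakpointRegression(RegressorMixin, BaseEstimator):
    """Two-segment continuous piecewise-linear regression with ML breakpoint
    search and simulation-calibrated delta-slope inference.

    Parameters
    ----------
    min_segment : int, default 3
        Minimum number of observations strictly on each side of a candidate
        breakpoint (3 is the least that leaves a defined slope plus a
        residual degree of freedom per segment).
    breakpoint_on : int, default 0
        Column of X that carries the breakpoint; any other column enters
        linearly (at most one extra column is supported, mirroring the
        one-breakpoint-at-a-time design).

    Attributes
    ----------
    intercept_, slope1_, delta_slope_, breakpoint_, covariate_coef_ : float
        ML estimates (b0, b1, b2, k, and the linear coefficient of the
        second cue if present).
    sigma2_, loglik_, r2_, n_obs_ : float
        Residual variance (SSE/n), profile log-likelihood, in-sample R^2, n.
    linear_fit_ : LinearFit
        The nested no-breakpoint fit on the same data.
    calibration_ : CalibratedInference or None
        Set by :meth:`calibrate`.

    Examples
    --------
    >>> import numpy as np
    >>> x = np.arange(20.0)
    >>> y = 1.0 + 0.0 * x + 0.8 * np.maximum(x - 10, 0)
    >>> m = BreakpointRegression().fit(x[:, None], y)
    >>> float(m.breakpoint_), round(m.delta_slope_, 6)
    (10.0, 0.8)
    """

    def __init__(self, min_segment: int = 3, breakpoint_on: int = 0):
        self.min_segment = min_segment
        self.breakpoint_on = breakpoint_on

    def _split_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] > 2:
            raise ValueError("at most two cue columns are supported")
        if self.breakpoint_on not in range(X.shape[1]):
            raise ValueError("breakpoint_on is out of range for X")
        x = X[:, self.breakpoint_on]
        other = [j for j in range(X.shape[1]) if j != self.breakpoint_on]
        x2 = X[:, other[0]] if other else None
        return x, x2

    def fit(self, X, y):
        x, x2 = self._split_X(X)
        fit = fit_breakpoint(x, np.asarray(y, dtype=float), x2, min_segment=self.min_segment)
        self.linear_fit_ = fit_linear(x, np.asarray(y, dtype=float), x2)
        self.intercept_ = fit.beta0
        self.slope1_ = fit.beta1
        self.delta_slope_ = fit.beta2
        self.breakpoint_ = fit.k
        self.covariate_coef_ = fit.gamma
        self.sigma2_ = fit.sigma2
        self.loglik_ = fit.loglik
        self.r2_ = fit.r2
        self.n_obs_ = fit.n
        self.fit_ = fit
        self.calibration_ = None
        return self

    def predict(self, X):
        x, x2 = self._split_X(X)
        yhat = self.intercept_ + self.slope1_ * x + self.delta_slope_ * _hinge(x, self.breakpoint_)
        if x2 is not None:
            if self.covariate_coef_ is None:
                raise ValueError("model was fitted without a second cue")
            yhat = yhat + self.covariate_coef_ * x2
        return yhat

    def calibrate(self, X, y, n_null: int = 1000, random_state=None) -> CalibratedInference:
        """Run the parametric-bootstrap null calibration on the training data."""
        x, x2 = self._split_X(X)
        self.calibration_ = null_calibration(
            x, np.asarray(y, dtype=float), x2,
            n_null=n_null, seed=random_state, min_segment=self.min_segment,
        )
        return self.calibration_

    @property
    def second_segment_slope_(self) -> float:
        return derive_second_segment_slope(self.slope1_, self.delta_slope_)
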