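"""Multilevel random-effects meta-regression of per-series slope estimates.

Each taxon-by-plot time series contributes one effect size (a slope-1 or
delta-slope estimate) with a known sampling variance (its squared
null-simulation standard error).  The community-level model is

    estimate_i = mu (+ moderators) + u_taxon(i) + u_plot(i) + u_taxon.plot(i) + e_i,

with u terms as independent Gaussian random intercepts (variance components
tau2 per level, REML-estimated, floored at zero) and e_i ~ N(0, v_i) with
v_i known.  The pooled estimate, its Wald-normal 95% CI, Cochran's Q
heterogeneity test and likelihood-ratio tests for the random terms mirror
standard multilevel meta-analytic practice (metafor's ``rma.mv``).

The REML objective is maximised directly over the variance components with
L-BFGS-B; problem sizes here (tens to low hundreds of records) make dense
linear algebra and a quasi-Newton search entirely adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "MetaResult",
    "RandomEffectsMeta",
    "fit_meta",
    "moderator_test",
    "q_test",
    "lrt_random_term",
]

DEFAULT_RANDOM_TERMS = ("taxon", "plot", "taxon:plot")
_Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MetaResult:
    """Pooled estimate and model summary for one effect-size set."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    tau2: dict  # variance component per random term
    q_stat: float
    q_df: int
    q_pvalue: float
    n_records: int
    loglik_reml: float
    beta: np.ndarray = field(default=None, repr=False)
    beta_se: np.ndarray = field(default=None, repr=False)


def _grouping_matrix(labels) -> np.ndarray:
    labels = pd.Series(labels).astype(str)
    codes, _ = pd.factorize(labels)
    Z = np.zeros((len(labels), codes.max() + 1))
    Z[np.arange(len(labels)), codes] = 1.0
    return Z


def _term_matrices(records: pd.DataFrame, random_terms) -> dict:
    out = {}
    for term in random_terms:
        if ":" in term:
            parts = term.split(":")
            lab = records[parts[0]].astype(str)
            for p in parts[1:]:
                lab = lab + "/" + records[p].astype(str)
        else:
            lab = records[term]
        out[term] = _grouping_matrix(lab)
    return out


def _reml_loglik(tau2: np.ndarray, y, X, v, ZZt_list):
    n, p = X.shape
    V = np.diag(v.copy())
    for t2, ZZt in zip(tau2, ZZt_list):
        V += t2 * ZZt
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    Vinv_X = np.linalg.solve(V, X)  # could reuse L; clarity over speed here
    Vinv_y = np.linalg.solve(V, y)
    XtVinvX = X.T @ Vinv_X
    try:
        beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    r = y - X @ beta
    Vinv_r = np.linalg.solve(V, r)
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    sign, logdetXtVX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return -np.inf, None, None
    # the + log|X'X| term is the lme/metafor REML convention; it cancels in
    # any likelihood-ratio comparison with shared fixed effects
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi) - logdetXtX + logdetV + logdetXtVX + float(r @ Vinv_r)
    )
    return ll, beta, np.linalg.inv(XtVinvX)


def _fit_reml(y, X, v, ZZt_list, n_restarts: int = 3):
    """Maximise the restricted likelihood over tau2 >= 0."""
    q = len(ZZt_list)
    if q == 0:
        ll, beta, covb = _reml_loglik(np.empty(0), y, X, v, [])
        return np.empty(0), ll, beta, covb

    def neg(tau2):
        ll, _, _ = _reml_loglik(np.maximum(tau2, 0.0), y, X, v, ZZt_list)
        return np.inf if not np.isfinite(ll) else -ll

    # moment-flavoured starting scale plus a zero start
    scale = max(float(np.var(y, ddof=1) - np.mean(v)), float(np.mean(v)), 1e-8)
    starts = [np.zeros(q), np.full(q, scale / q), np.full(q, 0.1 * scale)]
    best = None
    for s in starts[: max(1, n_restarts)]:
        res = optimize.minimize(
            neg, s, method="L-BFGS-B", bounds=[(0.0, None)] * q,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML optimisation failed to converge")
    tau2 = np.maximum(best.x, 0.0)
    ll, beta, covb = _reml_loglik(tau2, y, X, v, ZZt_list)
    return tau2, ll, beta, covb


def q_test(y, v, X=None):
    """Cochran's Q heterogeneity test with fixed-effect weights 1/v.

    Q is the weighted residual sum of squares around the fixed-effects
    (inverse-variance) fit of ``X`` (intercept-only by default), referred to
    chi-square with n - p degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    w = 1.0 / v
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X, XtW @ y)
    r = y - X @ beta
    q = float(np.sum(w * r**2))
    df = n - X.shape[1]
    return q, df, float(stats.chi2.sf(q, df))


class RandomEffectsMeta(BaseEstimator):
    """Multilevel random-effects meta-regression estimator.

    Parameters
    ----------
    random_terms : tuple of str, default ("taxon", "plot", "taxon:plot")
        Record columns (or colon-joined interactions) receiving random
        intercepts.  An empty tuple gives the fixed-effect (inverse-variance)
        model.
    moderator : str or None
        Optional record column added as a fixed-effect indicator/covariate.

    Attributes
    ----------
    estimate_, se_, ci_ : pooled intercept, its SE and Wald 95% CI.
    tau2_ : dict of REML variance components (zero when a component hits
        the boundary).
    result_ : MetaResult with the Q test and restricted log-likelihood.
    moderator_coef_, moderator_se_, moderator_p_ : set when a moderator is
        included (Wald z test).
    """

    def __init__(self, random_terms=DEFAULT_RANDOM_TERMS, moderator: str | None = None):
        self.random_terms = tuple(random_terms)
        self.moderator = moderator

    def fit(self, records: pd.DataFrame, y=None):
        req = {"estimate", "variance"}
        if not req.issubset(records.columns):
            raise ValueError("records need 'estimate' and 'variance' columns")
        if len(records) < 2:
            raise ValueError("need at least 2 effect-size records")
        yv = records["estimate"].to_numpy(dtype=float)
        v = records["variance"].to_numpy(dtype=float)
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("sampling variances must be positive and finite")

        X = np.ones((len(records), 1))
        mod_levels = None
        if self.moderator is not None:
            if self.moderator not in records.columns:
                raise ValueError(f"moderator column {self.moderator!r} missing")
            col = records[self.moderator]
            if col.dtype.kind in "OUSb":
                mod_levels = sorted(col.astype(str).unique())
                if len(mod_levels) != 2:
                    raise ValueError("categorical moderator must have two levels")
                X = np.column_stack([X[:, 0], (col.astype(str) == mod_levels[1]).astype(float)])
            else:
                X = np.column_stack([X[:, 0], col.to_numpy(dtype=float)])

        Zs = _term_matrices(records, self.random_terms)
        ZZt = [Z @ Z.T for Z in Zs.values()]
        tau2, ll, beta, covb = _fit_reml(yv, X, v, ZZt)
        se = np.sqrt(np.diag(covb))
        q, qdf, qp = q_test(yv, v, X)

        self.estimate_ = float(beta[0])
        self.se_ = float(se[0])
        self.ci_ = (self.estimate_ - _Z95 * self.se_, self.estimate_ + _Z95 * self.se_)
        self.tau2_ = {t: float(t2) for t, t2 in zip(self.random_terms, tau2)}
        self.loglik_reml_ = float(ll)
        if self.moderator is not None:
            self.moderator_coef_ = float(beta[1])
            self.moderator_se_ = float(se[1])
            z = self.moderator_coef_ / self.moderator_se_
            self.moderator_p_ = float(2.0 * stats.norm.sf(abs(z)))
            self.moderator_levels_ = mod_levels
        self.result_ = MetaResult(
            estimate=self.estimate_,
            se=self.se_,
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            tau2=self.tau2_,
            q_stat=q,
            q_df=qdf,
            q_pvalue=qp,
            n_records=len(records),
            loglik_reml=float(ll),
            beta=beta,
            beta_se=se,
        )
        return self


def fit_meta(records: pd.DataFrame, random_terms=DEFAULT_RANDOM_TERMS) -> MetaResult:
    """Pool effect sizes with random intercepts; see :class:`RandomEffectsMeta`."""
    return RandomEffectsMeta(random_terms=random_terms).fit(records).result_


def moderator_test(records: pd.DataFrame, moderator: str, random_terms=DEFAULT_RANDOM_TERMS):
    """Wald test of a two-level moderator (e.g. single vs combined predictor).

    Returns (coefficient, SE, p): the fixed-effect difference of the second
    level relative to the first, with the full random structure retained.
    """
    m = RandomEffectsMeta(random_terms=random_terms, moderator=moderator).fit(records)
    return m.moderator_coef_, m.moderator_se_, m.moderator_p_


def lrt_random_term(
    records: pd.DataFrame,
    full_terms,
    reduced_terms,
    moderator: str | None = None,
):
    """REML likelihood-ratio test for dropping random terms.

    ``reduced_terms`` must be a subset of ``full_terms`` and both models
    share the same fixed effects (a REML requirement).  The statistic
    2*(ll_full - ll_reduced) is referred to chi-square with df equal to the
    number of dropped variance components — conservative at the tau2 = 0
    boundary (the 50:50 chi-square mixture would halve the p-value).

    Returns (statistic, df, p).
    """
    full_terms = tuple(full_terms)
    reduced_terms = tuple(reduced_terms)
    if not set(reduced_terms).issubset(full_terms):
        raise ValueError("reduced_terms must be a subset of full_terms")
    if full_terms == reduced_terms:
        raise ValueError("full and reduced models are identical")
    m_full = RandomEffectsMeta(random_terms=full_terms, moderator=moderator).fit(records)
    m_red = RandomEffectsMeta(random_terms=reduced_terms, moderator=moderator).fit(records)
    stat = max(0.0, 2.0 * (m_full.loglik_reml_ - m_red.loglik_reml_))
    df = len(full_terms) - len(reduced_terms)
    return stat, df, float(stats.chi2.sf(stat, df))
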