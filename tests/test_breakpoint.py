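"""Breakpoint regression: ML search, nesting, calibration, derived slopes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phenobreak import breakpoint as bp
from phenobreak.breakpoint import BreakpointRegression
from phenobreak.simulate import ReactionNorm, generate_regression_set


def brute_force_breakpoint(x, y, x2=None, min_segment=3):
    """Independent exhaustive search recomputing least squares from scratch."""
    best = None
    for k in np.unique(x):
        if (x < k).sum() < min_segment or (x > k).sum() < min_segment:
            continue
        cols = [np.ones_like(x), x, np.where(x >= k, x - k, 0.0)]
        if x2 is not None:
            cols.append(x2)
        X = np.column_stack(cols)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        sse = float(np.sum((y - X @ beta) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, k, beta)
    return best


class TestLinearFit:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = bp.fit_linear(x, 2.0 * x)
        assert fit.beta1 == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_slope_vanishes_when_y_independent_of_x(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5000)
        fit = bp.fit_linear(x, rng.normal(size=5000))
        assert abs(fit.beta1) < 0.05

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(160, 8, 25)
        x2 = rng.normal(0, 1, 25)
        y = rng.normal(180, 5, 25)
        X = np.column_stack([np.ones(25), x, x2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = bp.fit_linear(x, y, x2)
        np.testing.assert_allclose([fit.beta0, fit.beta1, fit.gamma], beta, atol=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            bp.fit_linear(np.full(10, 3.0), np.arange(10.0))


class TestBreakpointSearch:
    def test_noiseless_exact_recovery(self):
        x = np.arange(20.0)
        y = 5.0 + 0.2 * x + 0.8 * np.maximum(x - 11.0, 0.0)
        fit = bp.fit_breakpoint(x, y)
        assert fit.k == 11.0
        assert fit.beta1 == pytest.approx(0.2, abs=1e-9)
        assert fit.beta2 == pytest.approx(0.8, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_noiseless_recovery_with_covariate(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.normal(160, 8, 24))
        x2 = rng.normal(0, 1, 24)
        k = x[10]
        y = 1.0 + 0.1 * x + 0.7 * np.where(x >= k, x - k, 0.0) - 2.0 * x2
        fit = bp.fit_breakpoint(x, y, x2)
        assert fit.k == k
        assert fit.gamma == pytest.approx(-2.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        x = rng.normal(160, 8, n)
        y = rng.normal(185, 4, n) + 0.3 * x
        fit = bp.fit_breakpoint(x, y)
        sse_o, k_o, beta_o = brute_force_breakpoint(x, y)
        assert fit.k == k_o
        assert fit.sse == pytest.approx(sse_o, abs=1e-8)
        np.testing.assert_allclose([fit.beta0, fit.beta1, fit.beta2], beta_o, atol=1e-8)

    def test_tie_breaks_toward_smallest_k(self):
        # perfectly symmetric flat data: every candidate fits equally well
        x = np.arange(12.0)
        y = np.full(12, 7.0)
        fit = bp.fit_breakpoint(x, y)
        assert fit.k == 3.0  # smallest admissible candidate (3 strictly below)

    def test_too_few_distinct_x(self):
        x = np.repeat([1.0, 2.0], 5)
        with pytest.raises(ValueError):
            bp.fit_breakpoint(x, np.arange(10.0))

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_nesting_invariant(self, seed):
        """Breakpoint log-likelihood never falls below the nested linear fit."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        x = rng.normal(0, 1, n)
        y = rng.normal(0, 1, n) + rng.uniform(-2, 2) * x
        try:
            fit = bp.fit_breakpoint(x, y)
        except ValueError:
            return  # too few admissible candidates for this draw
        lin = bp.fit_linear(x, y)
        assert fit.loglik >= lin.loglik - 1e-9
        assert fit.r2 >= lin.r2 - 1e-12
        assert fit.k in x


class TestNullCalibration:
    def test_degenerate_llr_zero_gives_p_one(self):
        # noise-free linear data: breakpoint model gains nothing
        x = np.arange(20.0)
        cal = bp.null_calibration(x, 3.0 + 2.0 * x, n_null=99, seed=0)
        assert cal.observed_llr == 0.0
        assert cal.p_delta == 1.0

    def test_vectorised_search_matches_scalar_fit(self):
        rng = np.random.default_rng(1)
        x = rng.normal(160, 8, 22)
        Y = 180 + 0.4 * x[:, None] + rng.normal(0, 3, (22, 8))
        sse, b1, b2, k, ok = bp._search_many(x, Y)
        assert ok.all()
        for j in range(Y.shape[1]):
            f = bp.fit_breakpoint(x, Y[:, j])
            assert f.k == k[j]
            assert f.sse == pytest.approx(sse[j], abs=1e-8)
            assert f.beta1 == pytest.approx(b1[j], abs=1e-8)
            assert f.beta2 == pytest.approx(b2[j], abs=1e-8)

    def test_se_beta1_exceeds_analytic_ols_se(self):
        """The null-sim slope-1 SE carries breakpoint-search noise on top of
        the analytic OLS slope SE: beta1 is re-estimated from the (often
        short) first segment of each refit, so its spread must exceed the
        full-data OLS SE while staying on a comparable scale."""
        rng = np.random.default_rng(2)
        x = np.linspace(144, 176, 25)
        y = 180 + 0.1 * x + rng.normal(0, 3, 25)
        lin = bp.fit_linear(x, y)
        X = np.column_stack([np.ones(25), x])
        se_ols = float(np.sqrt(lin.sigma2 * 25 / 23 * np.linalg.inv(X.T @ X)[1, 1]))
        cal = bp.null_calibration(x, y, n_null=2000, seed=3)
        assert cal.se_beta1 > se_ols
        assert cal.se_beta1 < 20 * se_ols

    def test_p_uniform_under_null(self):
        """Calibrated p-values are uniform on null data (KS at alpha=0.01)."""
        rng = np.random.default_rng(4)
        norm = ReactionNorm(delta_slope=0.0, slope_pre=0.1, residual_sd=3.0)
        ps = []
        for _ in range(200):
            rs = generate_regression_set(25, norm, seed=rng)
            ps.append(bp.null_calibration(rs.x, rs.y, n_null=199, seed=rng).p_delta)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_determinism(self):
        rng = np.random.default_rng(6)
        x = rng.normal(160, 8, 20)
        y = 180 + rng.normal(0, 3, 20)
        a = bp.null_calibration(x, y, n_null=100, seed=42)
        b = bp.null_calibration(x, y, n_null=100, seed=42)
        assert a == b


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "beta1, beta2, expected",
        [(0.12, 0.83, 0.95), (0.02, 0.69, 0.71), (-4.95, 4.20, -0.75)],
    )
    def test_second_segment_slope(self, beta1, beta2, expected):
        assert bp.derive_second_segment_slope(beta1, beta2) == pytest.approx(expected)

    def test_compare_r2(self):
        rng = np.random.default_rng(8)
        x = rng.normal(160, 8, 24)
        y = 180 + 0.5 * np.maximum(x - 160, 0) + rng.normal(0, 2, 24)
        lin = bp.fit_linear(x, y)
        fit = bp.fit_breakpoint(x, y)
        r2l, r2b = bp.compare_r2(lin, fit)
        sst = np.sum((y - y.mean()) ** 2)
        assert r2l == pytest.approx(1 - lin.sse / sst)
        assert r2b == pytest.approx(1 - fit.sse / sst)
        assert r2b >= r2l


class TestEstimatorInterface:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        m = BreakpointRegression(min_segment=4)
        m2 = clone(m)
        assert m2.get_params()["min_segment"] == 4

    def test_fit_predict_roundtrip(self):
        x = np.arange(20.0)
        y = 1.0 + 0.1 * x + 0.9 * np.maximum(x - 9.0, 0.0)
        m = BreakpointRegression().fit(x[:, None], y)
        np.testing.assert_allclose(m.predict(x[:, None]), y, atol=1e-8)
        assert m.breakpoint_ == 9.0
        assert m.second_segment_slope_ == pytest.approx(1.0, abs=1e-9)

    def test_covariate_column_selection(self):
        rng = np.random.default_rng(9)
        x = np.sort(rng.normal(160, 8, 24))
        x2 = rng.normal(0, 1, 24)
        k = x[12]
        y = 2.0 + 0.1 * x + 0.6 * np.where(x >= k, x - k, 0.0) + 1.5 * x2
        X = np.column_stack([x2, x])
        m = BreakpointRegression(breakpoint_on=1).fit(X, y)
        assert m.breakpoint_ == k
        assert m.covariate_coef_ == pytest.approx(1.5, abs=1e-8)
        cal = m.calibrate(X, y, n_null=50, random_state=0)
        assert 0 < cal.p_delta <= 1
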