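"""Multilevel random-effects meta-regression: pooling, moderators, LRTs."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenobreak.meta import (
    RandomEffectsMeta,
    fit_meta,
    lrt_random_term,
    moderator_test,
    q_test,
)


def make_records(rng, mu=0.4, tau_taxon=0.3, tau_plot=0.15, tau_combo=0.1,
                 n_taxa=6, n_plots=4, v_range=(0.02, 0.08)):
    ut = rng.normal(0, tau_taxon, n_taxa)
    up = rng.normal(0, tau_plot, n_plots)
    uc = rng.normal(0, tau_combo, (n_taxa, n_plots))
    v = rng.uniform(*v_range, (n_taxa, n_plots))
    est = mu + ut[:, None] + up[None, :] + uc + rng.normal(0, np.sqrt(v))
    return pd.DataFrame(
        {
            "estimate": est.ravel(),
            "variance": v.ravel(),
            "taxon": np.repeat([f"t{i}" for i in range(n_taxa)], n_plots),
            "plot": np.tile([f"p{j}" for j in range(n_plots)], n_taxa),
        }
    )


class TestPooling:
    def test_identical_estimates_pool_to_that_value(self):
        rec = pd.DataFrame(
            {"estimate": [0.7] * 6, "variance": [0.1, 0.2, 0.05, 0.3, 0.1, 0.2],
             "taxon": list("aabbcc"), "plot": ["p1", "p2"] * 3}
        )
        res = fit_meta(rec)
        assert res.estimate == pytest.approx(0.7, abs=1e-8)

    def test_fixed_effect_closed_form_without_random_terms(self):
        rec = pd.DataFrame({"estimate": [0.2, 0.8], "variance": [0.04, 0.09]})
        res = fit_meta(rec, random_terms=())
        w = 1.0 / rec.variance.to_numpy()
        assert res.estimate == pytest.approx(np.average(rec.estimate, weights=w))
        assert res.se == pytest.approx(np.sqrt(1.0 / w.sum()))

    def test_fixed_effect_closed_form_many_records(self):
        rng = np.random.default_rng(0)
        rec = make_records(rng)
        res = fit_meta(rec, random_terms=())
        w = 1.0 / rec.variance.to_numpy()
        assert res.estimate == pytest.approx(
            float(np.average(rec.estimate, weights=w)), abs=1e-10
        )

    def test_pooled_se_decreases_with_more_records(self):
        rng = np.random.default_rng(1)
        rec = make_records(rng, n_taxa=8, n_plots=6)
        se_half = fit_meta(rec.iloc[:24]).se
        se_full = fit_meta(rec).se
        assert se_full <= se_half + 1e-12

    def test_variance_components_nonnegative_and_ci_symmetric(self):
        rng = np.random.default_rng(2)
        res = fit_meta(make_records(rng))
        assert all(v >= 0 for v in res.tau2.values())
        half = 1.959963984540054 * res.se
        assert res.ci_low == pytest.approx(res.estimate - half)
        assert res.ci_high == pytest.approx(res.estimate + half)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_meta(pd.DataFrame({"estimate": [1.0], "variance": [0.1]}))
        with pytest.raises(ValueError):
            fit_meta(pd.DataFrame({"estimate": [1.0, 2.0], "variance": [0.1, -0.1]}))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestMetaforOracle:
    def test_reml_matches_rma_mv(self, tmp_path):
        """Pooled estimate, SE, variance components and REML log-likelihood
        agree with metafor's rma.mv on the same records."""
        rng = np.random.default_rng(7)
        rec = make_records(rng)
        rec["combo"] = rec["taxon"] + "." + rec["plot"]
        csv = tmp_path / "records.csv"
        rec.to_csv(csv, index=False)
        m = RandomEffectsMeta().fit(rec)
        script = (
            'suppressMessages(library(metafor));'
            f'd <- read.csv("{csv}");'
            'm <- rma.mv(estimate, variance, random=list(~1|taxon, ~1|plot, ~1|combo),'
            '            data=d, method="REML");'
            'cat(coef(m), m$se, m$sigma2, logLik(m), sep=",")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        ref = [float(v) for v in out.stdout.strip().split(",")]
        assert m.estimate_ == pytest.approx(ref[0], abs=1e-4)
        assert m.se_ == pytest.approx(ref[1], rel=1e-3)
        np.testing.assert_allclose(
            sorted(m.tau2_.values()), sorted(ref[2:5]), atol=1e-4
        )
        assert m.loglik_reml_ == pytest.approx(ref[5], abs=1e-3)


class TestModerator:
    @staticmethod
    def _two_condition_records(rng, delta=0.0, v=1e-6):
        rec = []
        for cond in ("single", "combined"):
            for i in range(6):
                rec.append(
                    {"estimate": 0.5 + (delta if cond == "combined" else 0.0)
                     + rng.normal(0, np.sqrt(v)),
                     "variance": v, "taxon": f"t{i}", "plot": "p1",
                     "model_type": cond}
                )
        return pd.DataFrame(rec)

    def test_identical_conditions_give_zero_coefficient(self):
        rng = np.random.default_rng(0)
        rec = self._two_condition_records(rng, delta=0.0, v=1e-10)
        coef, se, p = moderator_test(rec, "model_type", random_terms=("taxon",))
        assert coef == pytest.approx(0.0, abs=1e-4)

    def test_offset_recovered_with_tiny_variances(self):
        rng = np.random.default_rng(1)
        rec = self._two_condition_records(rng, delta=0.3, v=1e-8)
        coef, se, p = moderator_test(rec, "model_type", random_terms=("taxon",))
        # "combined" is the reference-coded second level
        assert abs(coef) == pytest.approx(0.3, abs=1e-3)
        assert p < 1e-6

    def test_null_moderator_type1_rate(self):
        """Wald test of a null moderator rejects at ~5%."""
        rng = np.random.default_rng(2)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            v = np.full(12, 0.04)
            rec = pd.DataFrame(
                {"estimate": 0.2 + rng.normal(0, np.sqrt(v)),
                 "variance": v,
                 "model_type": ["single"] * 6 + ["combined"] * 6}
            )
            _, _, p = moderator_test(rec, "model_type", random_terms=())
            rej += p < 0.05
        lo, hi = stats.binom.interval(0.999, n_rep, 0.05)
        assert lo <= rej <= hi

    def test_missing_condition_errors(self):
        rec = pd.DataFrame(
            {"estimate": [0.1, 0.2], "variance": [0.1, 0.1], "model_type": ["a", "a"]}
        )
        with pytest.raises(ValueError):
            moderator_test(rec, "model_type", random_terms=())


class TestQTest:
    def test_matches_hand_computed_weighted_ss(self):
        y = np.array([0.1, 0.5, 0.3, 0.9])
        v = np.array([0.04, 0.02, 0.05, 0.1])
        q, df, p = q_test(y, v)
        w = 1.0 / v
        mu = np.sum(w * y) / np.sum(w)
        assert q == pytest.approx(float(np.sum(w * (y - mu) ** 2)))
        assert df == 3
        assert p == pytest.approx(float(stats.chi2.sf(q, 3)))

    def test_mean_near_df_under_homogeneity(self):
        rng = np.random.default_rng(3)
        qs = []
        for _ in range(300):
            v = rng.uniform(0.02, 0.1, 10)
            y = 0.4 + rng.normal(0, np.sqrt(v))
            qs.append(q_test(y, v)[0])
        assert np.mean(qs) == pytest.approx(9.0, abs=0.6)

    def test_outlier_inflates_q(self):
        y = np.array([0.1, 0.12, 0.09, 0.11, 5.0])
        v = np.full(5, 0.01)
        q, df, p = q_test(y, v)
        assert p < 0.05


class TestLrt:
    def test_zero_variance_truth_concentrates_near_zero(self):
        rng = np.random.default_rng(4)
        stats_ = []
        for _ in range(60):
            v = np.full(20, 0.05)
            rec = pd.DataFrame(
                {"estimate": 0.3 + rng.normal(0, np.sqrt(v)), "variance": v,
                 "taxon": [f"t{i % 5}" for i in range(20)]}
            )
            s, df, p = lrt_random_term(rec, ("taxon",), ())
            stats_.append(s)
        assert np.median(stats_) < 0.5

    def test_large_variance_detected(self):
        rng = np.random.default_rng(5)
        ut = rng.normal(0, 1.0, 8)
        v = np.full(48, 0.02)
        rec = pd.DataFrame(
            {"estimate": 0.3 + np.repeat(ut, 6) + rng.normal(0, np.sqrt(v)),
             "variance": v, "taxon": np.repeat([f"t{i}" for i in range(8)], 6)}
        )
        s, df, p = lrt_random_term(rec, ("taxon",), ())
        assert s > 10
        assert p < 0.001

    def test_matches_profile_grid_oracle(self):
        """LRT statistic equals a brute-force profiled-likelihood grid search
        for the single-component model."""
        from phenobreak.meta import _reml_loglik

        rng = np.random.default_rng(6)
        ut = rng.normal(0, 0.4, 6)
        v = rng.uniform(0.02, 0.06, 30)
        taxon = np.repeat([f"t{i}" for i in range(6)], 5)
        rec = pd.DataFrame(
            {"estimate": 0.3 + np.repeat(ut, 5) + rng.normal(0, np.sqrt(v)),
             "variance": v, "taxon": taxon}
        )
        s, df, p = lrt_random_term(rec, ("taxon",), ())
        y = rec.estimate.to_numpy()
        X = np.ones((30, 1))
        Z = pd.get_dummies(rec.taxon).to_numpy(dtype=float)
        grid = np.concatenate([[0.0], np.geomspace(1e-6, 5.0, 4000)])
        lls = [_reml_loglik(np.array([t2]), y, X, v, [Z @ Z.T])[0] for t2 in grid]
        ll0 = _reml_loglik(np.empty(0), y, X, v, [])[0]
        oracle = 2.0 * (max(lls) - ll0)
        assert s == pytest.approx(max(oracle, 0.0), abs=1e-3)

    def test_non_nested_inputs_error(self):
        rec = make_records(np.random.default_rng(7))
        with pytest.raises(ValueError):
            lrt_random_term(rec, ("taxon",), ("plot",))
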