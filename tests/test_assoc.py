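"""Association tests: IRLS logistic fit vs statsmodels oracle, Nagelkerke
R^2, BH q-values, published two-sample/chi-square worked examples, and OLS
against the normal equations."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import logit

from erpmed.assoc import (
    RankDeficiencyError,
    SeparationError,
    fdr_adjust,
    logistic_fit,
    nagelkerke_r2,
    ols_fit,
    pearson_chi2,
    prs_association,
    two_sample_t,
)
from erpmed.containers import ConfigurationError


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        fit = logistic_fit(y, np.ones((100, 1)))
        assert fit.coef[0] == pytest.approx(logit(0.3), abs=1e-8)

    def test_matches_statsmodels_on_8_obs(self):
        y = np.array([0, 0, 1, 0, 1, 1, 1, 0.0])
        x = np.array([-1.2, 0.5, 0.3, -0.1, 0.8, 1.5, -0.2, -0.9])
        X = np.column_stack([np.ones(8), x])
        fit = logistic_fit(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_matches_statsmodels_on_random_instance(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(200), rng.normal(size=(200, 3))])
        y = (rng.random(200) < 1 / (1 + np.exp(-(X @ [0.2, 0.5, -0.3, 0.1])))
             ).astype(float)
        fit = logistic_fit(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.cov, ref.cov_params(), rtol=1e-4)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            x = rng.normal(size=500)
            y = (rng.random(500) < 0.5).astype(float)
            fit = logistic_fit(y, np.column_stack([np.ones(500), x]))
            hits += abs(fit.coef[1]) < 2 * fit.se[1]
        assert hits >= 93

    def test_perfect_separation_names_column(self):
        x = np.concatenate([-np.random.default_rng(2).random(20) - 0.1,
                            np.random.default_rng(3).random(20) + 0.1])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError, match="dose"):
            logistic_fit(y, np.column_stack([np.ones(40), x]),
                         names=["intercept", "dose"])

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(RankDeficiencyError):
            logistic_fit(y, X)


class TestNagelkerke:
    def test_no_improvement_zero(self):
        assert nagelkerke_r2(-50.0, -50.0, 100) == 0.0

    def test_hand_computation(self):
        # balanced binary null: ll0 = 100 ln(1/2); formula value 0.42713
        assert nagelkerke_r2(-69.3147, -50.0, 100) == pytest.approx(0.4272,
                                                                    abs=5e-4)

    def test_perfect_fit_normalizes_to_one(self):
        assert nagelkerke_r2(100 * np.log(0.5), 0.0, 100) == pytest.approx(1.0)


class TestFDR:
    def test_single_p(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup(self):
        q = fdr_adjust([0.001, 0.01, 0.02, 0.8])
        np.testing.assert_allclose(q, [0.004, 0.02, 0.02667, 0.8], atol=1e-5)

    def test_all_equal(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_order_invariance(self):
        p = [0.04, 0.001, 0.5, 0.01]
        q = fdr_adjust(p)
        perm = [1, 3, 0, 2]
        q_perm = fdr_adjust([p[i] for i in perm])
        np.testing.assert_allclose([q[i] for i in perm], q_perm)

    def test_invalid_p_rejected(self):
        with pytest.raises(ConfigurationError):
            fdr_adjust([0.0, 0.5])


class TestGroupComparisons:
    def test_age_comparison_all_subjects(self):
        # GI vs non-GI age contrast from the published summary statistics
        c = two_sample_t(43.58, 14.68, 60, 38.41, 13.25, 323)
        assert c.p == pytest.approx(0.007, abs=0.001)

    def test_age_comparison_cases_only(self):
        c = two_sample_t(45.02, 14.39, 55, 41.38, 12.68, 203)
        assert c.p == pytest.approx(0.07, abs=0.005)

    def test_identical_groups(self):
        c = two_sample_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert c.statistic == 0.0

    def test_zero_variance(self):
        c = two_sample_t(5.0, 0.0, 10, 5.0, 0.0, 10)
        assert (c.statistic, c.p) == (0.0, 1.0)
        with pytest.raises(ConfigurationError):
            two_sample_t(5.0, 0.0, 10, 6.0, 0.0, 10)

    @pytest.mark.parametrize("table, expected", [
        ([[29, 26, 5], [107, 96, 120]], 19.11),
        ([[30, 30], [171, 152]], 0.18),
        ([[24, 33], [77, 241]], 7.86),
        ([[26, 29], [120, 83]], 2.47),
        ([[24, 28], [69, 132]], 2.49),
    ])
    def test_published_contingency_tables(self, table, expected):
        c = pearson_chi2(table)
        assert round(c.statistic, 2) == expected

    def test_table_equal_to_expected_is_zero(self):
        c = pearson_chi2([[10, 20], [20, 40]])
        assert c.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ConfigurationError):
            pearson_chi2([[0, 0], [5, 5]])


class TestOLS:
    def test_exact_line(self):
        X = np.column_stack([np.ones(3), [1.0, 2, 3]])
        fit = ols_fit(np.array([1.0, 2, 3]), X)
        np.testing.assert_allclose(fit.coef, [0.0, 1.0], atol=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(30), rng.normal(size=(30, 3))])
        y = rng.normal(size=30)
        fit = ols_fit(y, X)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coef, oracle, atol=1e-10)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.pvalues, ref.pvalues, atol=1e-10)

    def test_recovers_planted_group_effect(self):
        """Adjusted linear model recovers a 4-point group effect on a
        PANSS-like outcome (noise SD 7, n = 161) within 2 SE almost always."""
        rng = np.random.default_rng(6)
        ok = 0
        for _ in range(50):
            n = 161
            gi = (rng.random(n) < 0.22).astype(float)
            age = rng.normal(40, 13, n)
            y = 16 + 4.0 * gi + 0.0 * age + rng.normal(0, 7, n)
            X = np.column_stack([np.ones(n), gi, age])
            fit = ols_fit(y, X)
            ok += abs(fit.coef[1] - 4.0) < 2 * fit.se[1]
        assert ok >= 45

    def test_collinearity_named(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        with pytest.raises(RankDeficiencyError):
            ols_fit(np.random.default_rng(0).normal(size=20), X)


class TestPRSAssociation:
    @staticmethod
    def _inputs(rng, n=383, effect=0.0):
        pcs = pd.DataFrame(rng.normal(size=(n, 3)), columns=["PC1", "PC2", "PC3"],
                           index=pd.Index([f"S{i}" for i in range(n)],
                                          name="sample_id"))
        rows = []
        score = {}
        for trait in ("a", "b", "c", "d"):
            for pt in (0.001, 0.01, 0.05, 0.1, 0.5):
                s = rng.normal(size=n)
                score[(trait, pt)] = s
                rows += [(f"S{i}", trait, pt, s[i], 10) for i in range(n)]
        prs = pd.DataFrame(rows, columns=["sample_id", "trait", "p_threshold",
                                          "score", "n_snps"])
        lin = effect * score[("a", 0.001)]
        gi = pd.Series((rng.random(n) < 1 / (1 + np.exp(-(-1.7 + lin)))).astype(int),
                       index=pcs.index)
        return prs, gi, pcs

    def test_twenty_results_per_subset(self):
        prs, gi, pcs = self._inputs(np.random.default_rng(7))
        res = prs_association(prs, gi, pcs, subset="all")
        assert len(res) == 20
        assert all(r.nagelkerke_r2 >= 0 for r in res)

    def test_null_delta_r2_small(self):
        rng = np.random.default_rng(8)
        r2s = []
        for _ in range(20):
            prs, gi, pcs = self._inputs(rng)
            res = prs_association(prs, gi, pcs)
            r2s += [r.nagelkerke_r2 for r in res]
        assert np.mean(r2s) < 0.01

    def test_powered_detection_of_generating_effect(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(25):
            prs, gi, pcs = self._inputs(rng, effect=0.5)
            res = prs_association(prs, gi, pcs)
            r = next(x for x in res if x.trait == "a" and x.p_threshold == 0.001)
            hits += (r.beta > 0) and (r.wald_p < 0.05)
        assert hits >= 20

    def test_constant_score_gives_zero_delta_r2(self):
        prs, gi, pcs = self._inputs(np.random.default_rng(10))
        prs.loc[(prs["trait"] == "a") & (prs["p_threshold"] == 0.5), "score"] = 1.0
        res = prs_association(prs, gi, pcs)
        r = next(x for x in res if x.trait == "a" and x.p_threshold == 0.5)
        assert r.nagelkerke_r2 == 0.0 and r.beta == 0.0

    def test_single_class_subset_rejected(self):
        prs, gi, pcs = self._inputs(np.random.default_rng(11))
        gi[:] = 1
        with pytest.raises(ConfigurationError):
            prs_association(prs, gi, pcs)
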