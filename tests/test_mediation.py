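"""Mediation tests: counterfactual effect formulas against a Monte-Carlo
oracle, exposure dichotomization, bootstrap behavior, parameter recovery,
and the unmeasured-confounding sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from erpmed.containers import ConfigurationError
from erpmed.mediation import (
    MediatorModelFit,
    OutcomeModelFit,
    bootstrap_bcci,
    dichotomize_exposure,
    estimate_effects,
    fit_and_estimate,
    sensitivity_unmeasured,
)

coef = st.floats(-2, 2, allow_nan=False)


def mc_counterfactual_linear(m, o, a, a_star, c, n, rng):
    """Independent oracle: simulate M under each exposure level and average
    the outcome model; E[Y(a, M(a'))] estimated by Monte Carlo."""
    def ey(a_out, a_med):
        M = rng.random(n) < expit(m.b0 + m.b1 * a_med + m.b2 @ c)
        return (o.t0 + o.t1 * a_out + o.t2 * M + o.t3 * a_out * M
                + o.t4 @ c).mean()
    nde = ey(a, a_star) - ey(a_star, a_star)
    nie = ey(a, a) - ey(a, a_star)
    return nde, nie


class TestEstimateEffects:
    def test_no_mediator_pathway(self):
        m = MediatorModelFit(0.3, 1.2, np.array([]))
        o = OutcomeModelFit(1.0, 2.0, 0.0, 0.0, np.array([]), "linear")
        r = estimate_effects(m, o)
        assert r.nie == 0.0 and r.proportion_mediated == 0.0

    def test_hand_example(self):
        m = MediatorModelFit(0.0, 1.0, np.array([]))
        o = OutcomeModelFit(0.0, 2.0, 3.0, 0.0, np.array([]), "linear")
        r = estimate_effects(m, o, 1.0, 0.0)
        assert r.nde == pytest.approx(2.0)
        assert r.nie == pytest.approx(3 * (expit(1) - 0.5), abs=1e-4)
        assert r.proportion_mediated == pytest.approx(0.2574, abs=1e-4)

    @pytest.mark.parametrize("interaction", [False, True])
    def test_matches_mc_oracle_linear(self, interaction):
        rng = np.random.default_rng(12)
        for _ in range(5):
            m = MediatorModelFit(rng.normal(), rng.normal(),
                                 rng.normal(0, 0.5, 2))
            o = OutcomeModelFit(rng.normal(), rng.normal(), rng.normal(),
                                rng.normal() if interaction else 0.0,
                                rng.normal(0, 0.5, 2), "linear")
            c = rng.normal(0, 1, 2)
            r = estimate_effects(m, o, 1.0, 0.0, c)
            nde, nie = mc_counterfactual_linear(m, o, 1.0, 0.0, c, 10**6, rng)
            se = 3.0 / np.sqrt(10**6)  # conservative MC error bound
            assert r.nde == pytest.approx(nde, abs=4 * se)
            assert r.nie == pytest.approx(nie, abs=4 * se)

    def test_linear_identity_exact(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            m = MediatorModelFit(rng.normal(), rng.normal(), np.array([]))
            o = OutcomeModelFit(*rng.normal(size=4), np.array([]), "linear")
            r = estimate_effects(m, o, 1.0, 0.0)
            assert r.total == pytest.approx(r.nde + r.nie, rel=1e-12)

    @given(b0=coef, b1=coef, t1=coef, t2=coef)
    @settings(max_examples=50, deadline=None)
    def test_nde_ignores_mediator_model_without_interaction(self, b0, b1, t1, t2):
        o = OutcomeModelFit(0.0, t1, t2, 0.0, np.array([]), "linear")
        r1 = estimate_effects(MediatorModelFit(b0, b1, np.array([])), o)
        r2 = estimate_effects(MediatorModelFit(-b0, 2 * b1, np.array([])), o)
        assert r1.nde == pytest.approx(t1) == pytest.approx(r2.nde)

    def test_zero_total_flags_pm_undefined(self):
        m = MediatorModelFit(0.0, 0.0, np.array([]))
        o = OutcomeModelFit(0.0, 0.0, 0.0, 0.0, np.array([]), "linear")
        r = estimate_effects(m, o)
        assert not r.pm_defined and np.isnan(r.proportion_mediated)

    def test_logistic_rare_outcome_against_mc(self):
        rng = np.random.default_rng(14)
        m = MediatorModelFit(-0.5, 1.0, np.array([]))
        o = OutcomeModelFit(-6.5, 0.5, 0.8, 0.0, np.array([]), "logistic")
        r = estimate_effects(m, o)

        n = 2 * 10**6
        def odds(a_out, a_med):
            M = rng.random(n) < expit(m.b0 + m.b1 * a_med)
            p = (rng.random(n) < expit(o.t0 + o.t1 * a_out + o.t2 * M)).mean()
            return p / (1 - p)
        log_or_nde = np.log(odds(1, 0) / odds(0, 0))
        log_or_nie = np.log(odds(1, 1) / odds(1, 0))
        assert r.nde == pytest.approx(log_or_nde, abs=0.12)
        assert r.nie == pytest.approx(log_or_nie, abs=0.12)


class TestDichotomize:
    def test_rank_example(self):
        s = pd.Series(np.arange(1.0, 9.0))
        a = dichotomize_exposure(s)
        assert list(a.dropna().index) == [0, 1, 6, 7]
        assert a.iloc[0] == 0 and a.iloc[7] == 1

    def test_degenerate_rejected(self):
        with pytest.raises(ConfigurationError, match="degenerate"):
            dichotomize_exposure(pd.Series(np.ones(20)))

    def test_uniform_subset_near_half(self):
        s = pd.Series(np.random.default_rng(0).random(383))
        a = dichotomize_exposure(s)
        assert a.notna().sum() == pytest.approx(383 / 2, abs=10)


def _synthetic_mediation_data(rng, n=300, b1=1.0, t1=1.0, t2=3.0, t3=0.0,
                              sd=2.0):
    a = (rng.random(n) < 0.5).astype(float)
    age = rng.normal(0, 1, n)
    m = (rng.random(n) < expit(-0.5 + b1 * a + 0.2 * age)).astype(float)
    y = 1.0 + t1 * a + t2 * m + t3 * a * m + 0.3 * age + rng.normal(0, sd, n)
    return pd.DataFrame({"y": y, "m": m, "a": a, "age": age})


class TestFitAndEstimate:
    def test_full_mediation_recovered(self):
        rng = np.random.default_rng(15)
        covered = 0
        for s in range(20):
            d = _synthetic_mediation_data(rng, t1=0.0, t2=3.0)
            r = bootstrap_bcci(d, "y", "m", "a", ["age"], n_boot=100, seed=s)
            covered += r.ci_pm[0] <= 1.0 <= r.ci_pm[1]
        assert covered >= 16

    def test_no_exposure_mediator_path_gives_null_nie(self):
        rng = np.random.default_rng(16)
        covered = 0
        for s in range(20):
            d = _synthetic_mediation_data(rng, b1=0.0)
            r = bootstrap_bcci(d, "y", "m", "a", ["age"], n_boot=100, seed=s)
            covered += r.ci_nie[0] <= 0.0 <= r.ci_nie[1]
        assert covered >= 18

    def test_interaction_estimates_stable_when_truth_has_none(self):
        rng = np.random.default_rng(17)
        d = _synthetic_mediation_data(rng, n=2000, t3=0.0)
        r0 = fit_and_estimate(d, "y", "m", "a", ["age"], interaction=False)
        r1 = fit_and_estimate(d, "y", "m", "a", ["age"], interaction=True)
        boot = bootstrap_bcci(d, "y", "m", "a", ["age"], n_boot=100, seed=0)
        se_proxy = (boot.ci_nde[1] - boot.ci_nde[0]) / 3.92
        assert abs(r1.nde - r0.nde) < 0.5 * se_proxy + 1e-9 or \
            abs(r1.nde - r0.nde) < 0.25

    def test_constant_mediator_rejected(self):
        rng = np.random.default_rng(18)
        d = _synthetic_mediation_data(rng)
        d["m"] = 1.0
        with pytest.raises(ConfigurationError, match="mediator"):
            fit_and_estimate(d, "y", "m", "a", ["age"])


class TestBootstrap:
    def test_fixed_seed_deterministic(self):
        d = _synthetic_mediation_data(np.random.default_rng(19))
        r1 = bootstrap_bcci(d, "y", "m", "a", ["age"], n_boot=100, seed=5)
        r2 = bootstrap_bcci(d, "y", "m", "a", ["age"], n_boot=100, seed=5)
        assert r1.ci_nde == r2.ci_nde and r1.ci_nie == r2.ci_nie

    def test_nominal_coverage_of_nie(self):
        """Over simulated datasets with known NIE, the 95% BCCI covers the
        truth at close to nominal rate."""
        rng = np.random.default_rng(20)
        b1, t2 = 1.0, 3.0
        nie_true = t2 * (expit(-0.5 + b1) - expit(-0.5))  # age at its mean 0
        covered = 0
        n_rep = 60
        for s in range(n_rep):
            d = _synthetic_mediation_data(rng, b1=b1, t2=t2)
            r = bootstrap_bcci(d, "y", "m", "a", ["age"], n_boot=100, seed=s)
            covered += r.ci_nie[0] <= nie_true <= r.ci_nie[1]
        assert 0.85 * n_rep <= covered <= n_rep

    def test_small_n_boot_rejected(self):
        d = _synthetic_mediation_data(np.random.default_rng(21))
        with pytest.raises(ConfigurationError):
            bootstrap_bcci(d, "y", "m", "a", ["age"], n_boot=10)


class TestSensitivity:
    def test_zero_strength_reproduces_unadjusted_exactly(self):
        d = _synthetic_mediation_data(np.random.default_rng(22))
        base = fit_and_estimate(d, "y", "m", "a", ["age"])
        sens = sensitivity_unmeasured(d, "y", "m", "a", ["age"],
                                      strengths=[(0.0, 0.0)], n_draws=5)
        assert sens.nde[(0.0, 0.0)] == base.nde
        assert sens.nie[(0.0, 0.0)] == base.nie

    def test_stronger_outcome_confounding_attenuates_nie(self):
        d = _synthetic_mediation_data(np.random.default_rng(23), n=1500)
        sens = sensitivity_unmeasured(
            d, "y", "m", "a", ["age"],
            strengths=[(0.0, 0.0), (0.3, 0.3), (0.5, 0.5)],
            n_draws=40, seed=1)
        nies = [abs(sens.nie[k]) for k in [(0.0, 0.0), (0.3, 0.3), (0.5, 0.5)]]
        assert nies[2] < nies[1] < nies[0]

    def test_planted_confounder_recovered(self):
        """Data generated WITH a real mediator-outcome confounder: adjusting
        at the matching strength moves the NIE estimate toward the truth."""
        rng = np.random.default_rng(24)
        better = 0
        n_rep = 30
        for s in range(n_rep):
            n = 500
            a = (rng.random(n) < 0.5).astype(float)
            u = rng.normal(0, 1, n)
            m = (rng.random(n) < expit(-0.5 + 1.0 * a + 1.0 * u)).astype(float)
            y = 1.0 + 1.0 * a + 0.0 * m + 1.5 * u + rng.normal(0, 1.5, n)
            d = pd.DataFrame({"y": y, "m": m, "a": a})
            unadj = fit_and_estimate(d, "y", "m", "a", [])
            sens = sensitivity_unmeasured(d, "y", "m", "a", [],
                                          strengths=[(0.4, 0.4)], n_draws=30,
                                          seed=s)
            adj = sens.nie[(0.4, 0.4)]
            better += abs(adj - 0.0) < abs(unadj.nie - 0.0)
        assert better >= 0.75 * n_rep

    def test_infeasible_strengths_rejected(self):
        d = _synthetic_mediation_data(np.random.default_rng(25))
        with pytest.raises(ConfigurationError, match="infeasible"):
            sensitivity_unmeasured(d, "y", "m", "a", ["age"],
                                   strengths=[(0.9, -0.9)], n_draws=2)

    def test_liability_scale_runs(self):
        d = _synthetic_mediation_data(np.random.default_rng(26))
        sens = sensitivity_unmeasured(d, "y", "m", "a", ["age"],
                                      strengths=[(0.3, 0.3)], n_draws=5,
                                      mediator_scale="liability")
        assert np.isfinite(sens.nie[(0.3, 0.3)])
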