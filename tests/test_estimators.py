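"""Point estimators: exact identities, hand-computed oracles, bias structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvmr import (
    IdentificationError,
    IndividualDataset,
    ScenarioConfig,
    SummaryDataset,
    fit_ivw,
    fit_mvmr_egger,
    fit_mvmr_ivw,
    fit_ols,
    fit_tsls,
    simulate_scenario,
)
from mvmr.exceptions import RankError


def _k1_summary(pi, gamma, var_gamma):
    L = len(pi)
    return SummaryDataset(
        pi_hat=np.asarray(pi, float).reshape(L, 1),
        gamma_hat=gamma,
        var_pi=np.full((L, 1), 1e-4),
        var_gamma=var_gamma,
    )


class TestOLS:
    def test_exact_recovery_without_confounding(self):
        rng = np.random.default_rng(0)
        X1 = rng.normal(size=50)
        d = IndividualDataset(G=rng.integers(0, 3, (50, 2)).astype(float),
                              X=X1, Y=3.0 * X1)
        est = fit_ols(d)
        assert est.coef[0] == pytest.approx(3.0, abs=1e-10)
        lo, hi = est.ci[0]
        assert lo <= est.coef[0] <= hi

    def test_biased_under_confounding(self):
        cfg = ScenarioConfig.for_scenario("confounder", n=50_000, sd_u=1.0, seed=17)
        d = simulate_scenario(cfg)
        est = fit_ols(d, exposures=[0, 1])
        assert abs(est["x1"] - cfg.beta1) > 4 * est.se[0]

    def test_collinear_exposures_rejected(self):
        rng = np.random.default_rng(1)
        X1 = rng.normal(size=40)
        d = IndividualDataset(G=np.zeros((40, 2)), X=np.column_stack([X1, X1]),
                              Y=rng.normal(size=40))
        with pytest.raises(RankError):
            fit_ols(d)


class TestTSLS:
    def test_noiseless_mediator_recovers_both_effects_exactly(self):
        cfg = ScenarioConfig.for_scenario(
            "mediator", n=400, beta1=1.0, beta2=0.5, alpha1=2.0,
            sd_u=0.0, sd_vx1=0.0, sd_vx2=0.0, sd_vy=0.0, seed=2,
        )
        est = fit_tsls(simulate_scenario(cfg))
        np.testing.assert_allclose(est.coef, [1.0, 0.5], atol=1e-8)

    def test_single_snp_equals_wald_ratio(self):
        rng = np.random.default_rng(3)
        n = 500
        G = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        X = 0.5 * G[:, 0] + rng.normal(size=n)
        Y = 1.2 * X + rng.normal(size=n)
        d = IndividualDataset(G=G, X=X, Y=Y)
        est = fit_tsls(d, exposures=[0], instruments=[0])
        gc = G[:, 0] - G[:, 0].mean()
        wald = (gc @ Y) / (gc @ X)  # Gamma_hat / pi_hat from the same data
        assert est.coef[0] == pytest.approx(wald, rel=1e-10)

    def test_under_identified_rejected(self):
        rng = np.random.default_rng(4)
        d = IndividualDataset(G=rng.integers(0, 3, (100, 1)).astype(float),
                              X=rng.normal(size=(100, 2)), Y=rng.normal(size=100))
        with pytest.raises(IdentificationError):
            fit_tsls(d, exposures=[0, 1], instruments=[0])

    def test_univariable_biased_but_multivariable_unbiased_in_pleiotropy(self):
        cfg = ScenarioConfig.for_scenario("pleiotropy", n=100_000, seed=19)
        d = simulate_scenario(cfg)
        uni = fit_tsls(d, exposures=[0])
        mv = fit_tsls(d, exposures=[0, 1])
        assert abs(uni["x1"] - cfg.beta1) > 4 * uni.se[0]
        assert abs(mv["x1"] - cfg.beta1) < 4 * mv.se[0]

    def test_collider_safety(self):
        """MVMR is unbiased for beta1 when X2 is a collider; OLS adjusting
        directly for X2 is biased."""
        cfg = ScenarioConfig.for_scenario("collider", n=100_000, seed=23)
        d = simulate_scenario(cfg)
        mv = fit_tsls(d, exposures=[0, 1])
        ols = fit_ols(d, exposures=[0, 1])
        assert abs(mv["x1"] - cfg.beta1) < 4 * mv.se[0]
        assert abs(ols["x1"] - cfg.beta1) > 4 * ols.se[0]


class TestIVW:
    def test_exact_proportionality(self):
        rng = np.random.default_rng(5)
        pi = rng.uniform(0.2, 0.7, 6)
        est = fit_ivw(_k1_summary(pi, 2.0 * pi, np.full(6, 0.01)))
        assert est.coef[0] == pytest.approx(2.0, abs=1e-12)
        assert est.n_snps == 6

    def test_single_snp_collapses_to_wald_ratio(self):
        est = fit_ivw(_k1_summary([0.4], [0.9], [0.01]))
        assert est.coef[0] == pytest.approx(0.9 / 0.4, rel=1e-12)

    def test_four_snp_hand_weighted_mean(self):
        # weights pi^2/var_gamma: 16, 36, 16, 25; weighted mean = 197/93
        est = fit_ivw(_k1_summary([0.2, 0.3, 0.4, 0.5],
                                  [0.5, 0.55, 0.9, 1.1],
                                  [0.0025, 0.0025, 0.01, 0.01]))
        assert est.coef[0] == pytest.approx(197.0 / 93.0, rel=1e-12)

    def test_degenerate_instruments_rejected(self):
        with pytest.raises(ValueError):
            fit_ivw(_k1_summary([0.0, 0.0], [0.1, 0.2], [0.01, 0.01]))


class TestMVMRIVW:
    def test_exact_linear_combination(self, toy_summary):
        est = fit_mvmr_ivw(toy_summary)
        np.testing.assert_allclose(est.coef, [2.0, 3.0], atol=1e-10)

    def test_k1_reduces_to_ivw(self):
        rng = np.random.default_rng(6)
        s = _k1_summary(rng.uniform(0.1, 0.6, 8),
                        rng.normal(size=8), rng.uniform(0.01, 0.05, 8))
        a = fit_mvmr_ivw(s)
        b = fit_ivw(s)
        assert a.coef[0] == pytest.approx(b.coef[0], rel=1e-12)
        assert a.se[0] == pytest.approx(b.se[0], rel=1e-12)

    def test_under_identified_rejected(self):
        s = SummaryDataset(pi_hat=np.array([[0.3, 0.2]]), gamma_hat=[0.5],
                           var_pi=np.array([[0.01, 0.01]]), var_gamma=[0.01])
        with pytest.raises(IdentificationError):
            fit_mvmr_ivw(s)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(c=st.floats(0.05, 20.0))
    def test_scale_equivariance(self, c):
        """Scaling one exposure's effect column by c divides its coefficient by c."""
        rng = np.random.default_rng(99)
        L = 10
        pi = np.column_stack([rng.uniform(0.2, 0.8, L), rng.uniform(0.2, 0.8, L)])
        s = SummaryDataset(pi_hat=pi, gamma_hat=rng.normal(size=L),
                           var_pi=np.full((L, 2), 0.01), var_gamma=np.full(L, 0.02))
        base = fit_mvmr_ivw(s)
        scaled = SummaryDataset(pi_hat=pi * np.array([c, 1.0]),
                                gamma_hat=s.gamma_hat,
                                var_pi=s.var_pi, var_gamma=s.var_gamma)
        est = fit_mvmr_ivw(scaled)
        assert est.coef[0] == pytest.approx(base.coef[0] / c, rel=1e-8)
        assert est.coef[1] == pytest.approx(base.coef[1], rel=1e-8)


class TestMVMREgger:
    def test_no_pleiotropy_gives_zero_intercept(self, toy_summary):
        est = fit_mvmr_egger(toy_summary)
        assert est["intercept"] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(est.coef[1:], [2.0, 3.0], atol=1e-9)

    def test_affine_equivariance_of_intercept(self, toy_summary):
        shifted = SummaryDataset(
            pi_hat=toy_summary.pi_hat,
            gamma_hat=toy_summary.gamma_hat + 0.1,  # pi_hat >= 0: orientation is identity
            var_pi=toy_summary.var_pi,
            var_gamma=toy_summary.var_gamma,
            cov_pi=toy_summary.cov_pi,
        )
        base = fit_mvmr_egger(toy_summary)
        est = fit_mvmr_egger(shifted)
        assert est["intercept"] == pytest.approx(base["intercept"] + 0.1, abs=1e-9)
        np.testing.assert_allclose(est.coef[1:], base.coef[1:], atol=1e-9)

    def test_orientation_choice_does_not_move_slopes(self, both_identified_summary):
        a = fit_mvmr_egger(both_identified_summary, orient_to=0)
        b = fit_mvmr_egger(both_identified_summary, orient_to=1)
        for k in (1, 2):
            assert abs(a.coef[k] - b.coef[k]) < 2 * max(a.se[k], b.se[k])

    def test_too_few_snps_rejected(self):
        s = SummaryDataset(pi_hat=np.array([[0.3, 0.2], [0.1, 0.4]]),
                           gamma_hat=[0.5, 0.3],
                           var_pi=np.full((2, 2), 0.01), var_gamma=[0.01, 0.01])
        with pytest.raises(IdentificationError):
            fit_mvmr_egger(s)
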