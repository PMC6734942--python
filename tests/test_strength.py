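"""Instrument-strength diagnostics: F statistics, Sargan, delta-hat and Qx."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mvmr import (
    IdentificationError,
    IndividualDataset,
    ScenarioConfig,
    SummaryDataset,
    conditional_f,
    conventional_f,
    estimate_delta,
    q_strength,
    sargan_test,
    simulate_genotypes,
    simulate_identification_design,
    simulate_scenario,
)


def _strength_summary(seed=0, L=10, delta=0.6, noise=0.02):
    """Summary fixture: pi1 approximately delta * pi2, known covariances."""
    rng = np.random.default_rng(seed)
    pi2 = rng.uniform(0.3, 1.0, L)
    var1 = rng.uniform(0.005, 0.02, L)
    var2 = rng.uniform(0.005, 0.02, L)
    cov = 0.3 * np.sqrt(var1 * var2)
    pi1 = delta * pi2 + rng.normal(0, noise, L)
    return SummaryDataset(
        pi_hat=np.column_stack([pi1, pi2]),
        gamma_hat=np.zeros(L),
        var_pi=np.column_stack([var1, var2]),
        var_gamma=np.full(L, 0.01),
        cov_pi=cov.reshape(L, 1),
    )


class TestConventionalF:
    def test_null_calibration(self):
        """Exposure independent of G: mean F near 1, 5% rejection near nominal."""
        rng = np.random.default_rng(31)
        reps, n, L = 500, 300, 5
        f_vals = np.empty(reps)
        p_vals = np.empty(reps)
        for r in range(reps):
            G = rng.binomial(2, 0.3, size=(n, L)).astype(float)
            d = IndividualDataset(G=G, X=rng.normal(size=n), Y=np.zeros(n))
            stat = conventional_f(d)
            f_vals[r], p_vals[r] = stat.value, stat.p_value
        assert abs(f_vals.mean() - 1.0) < 0.15
        rej = np.mean(p_vals < 0.05)
        assert 0.02 < rej < 0.08

    def test_exact_linear_exposure_overflows_to_cap(self):
        G = simulate_genotypes(100, 3, seed=1)
        d = IndividualDataset(G=G, X=G @ np.array([1.0, 2.0, 3.0]), Y=np.zeros(100))
        stat = conventional_f(d)
        assert stat.value >= 1e14
        assert stat.p_value == pytest.approx(0.0, abs=1e-12)

    def test_strong_design_passes_rule_of_thumb(self, both_identified_data):
        for k in (0, 1):
            assert conventional_f(both_identified_data, exposure=k).value > 10.0


class TestConditionalF:
    def test_matches_statsmodels_four_step_recipe(self):
        """The 4-step construction, done independently with statsmodels on a
        50-subject 4-SNP toy, gives the identical statistic."""
        rng = np.random.default_rng(41)
        n, L = 50, 4
        G = rng.binomial(2, 0.4, size=(n, L)).astype(float)
        X1 = G @ rng.uniform(0.2, 0.5, L) + rng.normal(size=n)
        X2 = G @ rng.uniform(0.2, 0.5, L) + rng.normal(size=n)
        d = IndividualDataset(G=G, X=np.column_stack([X1, X2]), Y=np.zeros(n))

        W = sm.add_constant(G)
        x2hat = sm.OLS(X2, W).fit().fittedvalues          # step 1
        step2 = sm.OLS(X1, sm.add_constant(x2hat)).fit()  # step 2 (TSLS delta)
        resid = X1 - step2.params[0] - step2.params[1] * X2
        step3 = sm.OLS(resid, W).fit()                    # step 3
        f3 = step3.fvalue
        K = 2
        expected = f3 * L / (L - K + 1)                   # step 4 df correction

        stat = conditional_f(d, target_exposure=0)
        assert stat.value == pytest.approx(expected, rel=1e-8)
        assert stat.df[0] == L - K + 1

    def test_reduces_to_conventional_f_for_independent_exposures(self):
        """Disjoint SNP sets and independent noises: conditioning on the
        other exposure leaves the strength of the target essentially
        unchanged (Fc differs from F only through the df rescaling)."""
        rng = np.random.default_rng(43)
        n, L = 50_000, 30
        G = rng.binomial(2, 0.3, size=(n, L)).astype(float)
        pi1 = np.r_[rng.uniform(0.1, 0.3, 15), np.zeros(15)]
        pi2 = np.r_[np.zeros(15), rng.uniform(0.1, 0.3, 15)]
        X1 = G @ pi1 + rng.normal(size=n)
        X2 = G @ pi2 + rng.normal(size=n)
        d = IndividualDataset(G=G, X=np.column_stack([X1, X2]), Y=np.zeros(n))
        fc = conditional_f(d, target_exposure=0).value
        f = conventional_f(d, exposure=0).value
        assert abs(fc - f) / f < 0.10

    def test_proportional_effects_weak_jointly_but_strong_individually(self):
        """Shared SNP effects (pi1 = pi2) with a common confounder: each
        exposure is individually strong but conditionally weak."""
        d = simulate_identification_design(
            "jointly_unidentified", n=20_000, L=30, delta_design=1.0, seed=47
        )
        for k in (0, 1):
            assert conventional_f(d, exposure=k).value > 10.0
            assert conditional_f(d, target_exposure=k).value < 10.0


class TestSargan:
    def test_exactly_identified_model_not_computable(self):
        rng = np.random.default_rng(51)
        d = IndividualDataset(G=rng.binomial(2, 0.3, (100, 2)).astype(float),
                              X=rng.normal(size=(100, 2)), Y=rng.normal(size=100))
        with pytest.raises(IdentificationError):
            sargan_test(d)

    def test_noiseless_exact_model_gives_zero(self):
        cfg = ScenarioConfig.for_scenario(
            "pleiotropy", n=300, sd_u=0.0, sd_vx1=0.0, sd_vx2=0.0, sd_vy=0.0, seed=52
        )
        stat = sargan_test(simulate_scenario(cfg))
        assert stat.value == pytest.approx(0.0, abs=1e-6)

    def test_null_calibration_matches_chi2_reference(self):
        """No-pleiotropy mediator data: Sargan ~ chi2(L-K) = chi2(28)."""
        reps = 400
        vals = np.empty(reps)
        pvals = np.empty(reps)
        rngs = np.random.SeedSequence(53).spawn(reps)
        for r, ss in enumerate(rngs):
            cfg = ScenarioConfig.for_scenario("mediator", n=2_000, alpha1=0.5,
                                              seed=np.random.default_rng(ss))
            stat = sargan_test(simulate_scenario(cfg))
            vals[r], pvals[r] = stat.value, stat.p_value
        assert stat.df[0] == 28
        se_mean = np.sqrt(2 * 28 / reps)
        assert abs(vals.mean() - 28) < 3.5 * se_mean
        rej = np.mean(pvals < 0.05)
        assert 0.03 < rej < 0.08


class TestEstimateDelta:
    def test_exact_proportionality_recovered_with_zero_q(self):
        s = _strength_summary(seed=1, delta=1.7, noise=0.0)
        d_hat, _ = estimate_delta(s, target=0)
        assert d_hat == pytest.approx(1.7, abs=1e-9)
        assert q_strength(s, target=0).value == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self):
        s = _strength_summary(seed=2)
        d0, _ = estimate_delta(s, target=0)
        c = 3.5
        scaled = SummaryDataset(
            pi_hat=s.pi_hat * np.array([c, 1.0]),
            gamma_hat=s.gamma_hat,
            var_pi=s.var_pi * np.array([c**2, 1.0]),
            var_gamma=s.var_gamma,
            cov_pi=s.cov_pi * c,
        )
        d1, _ = estimate_delta(scaled, target=0)
        assert d1 == pytest.approx(c * d0, rel=1e-6)

    def test_matches_fine_grid_search_minimizer(self):
        """delta-hat agrees with a 1e-6-step grid search minimizing Qx."""
        s = _strength_summary(seed=3, L=10)
        d_hat, _ = estimate_delta(s, target=0)

        y, x = s.pi_hat[:, 0], s.pi_hat[:, 1]
        v1, v2 = s.var_pi[:, 0], s.var_pi[:, 1]
        c12 = s.cov_pi[:, 0]

        def q_of(d):
            sig = v1 + d * d * v2 - 2 * d * c12
            return np.sum((y - d * x) ** 2 / sig)

        coarse = np.arange(d_hat - 0.05, d_hat + 0.05, 1e-4)
        c_best = coarse[np.argmin([q_of(g) for g in coarse])]
        fine = np.arange(c_best - 2e-4, c_best + 2e-4, 1e-6)
        grid_min = fine[np.argmin([q_of(g) for g in fine])]
        assert abs(d_hat - grid_min) <= 1.0e-6


class TestQStrength:
    def test_per_snp_loop_equals_vectorized_value(self):
        s = _strength_summary(seed=4)
        stat = q_strength(s, target=0)
        d_hat = float(np.atleast_1d(stat.nuisance["delta"])[0])
        total = 0.0
        for j in range(s.L):
            sig = s.var_pi[j, 0] + d_hat**2 * s.var_pi[j, 1] - 2 * d_hat * s.cov_pi[j, 0]
            total += (s.pi_hat[j, 0] - d_hat * s.pi_hat[j, 1]) ** 2 / sig
        assert stat.value == pytest.approx(total, rel=1e-12)
        assert stat.value == pytest.approx(stat.per_snp.sum(), rel=1e-12)
        assert stat.p_value == pytest.approx(stats.chi2.sf(total, s.L - 1), rel=1e-10)

    def test_snp_reordering_invariance(self):
        s = _strength_summary(seed=5)
        perm = np.random.default_rng(0).permutation(s.L)
        sp = SummaryDataset(pi_hat=s.pi_hat[perm], gamma_hat=s.gamma_hat[perm],
                            var_pi=s.var_pi[perm], var_gamma=s.var_gamma[perm],
                            cov_pi=s.cov_pi[perm])
        assert q_strength(sp, 0).value == pytest.approx(q_strength(s, 0).value, rel=1e-10)

    def test_swapping_exposure_roles_maps_qx1_onto_qx2(self):
        s = _strength_summary(seed=6)
        swapped = SummaryDataset(pi_hat=s.pi_hat[:, ::-1], gamma_hat=s.gamma_hat,
                                 var_pi=s.var_pi[:, ::-1], var_gamma=s.var_gamma,
                                 cov_pi=s.cov_pi)
        assert q_strength(swapped, target=1).value == pytest.approx(
            q_strength(s, target=0).value, rel=1e-10
        )

    def test_assumed_zero_covariance_is_recorded_and_differs(self):
        s = _strength_summary(seed=7)
        known = q_strength(s, target=0, cov_mode="known")
        azero = q_strength(s, target=0, cov_mode="assumed_zero")
        assert known.cov_mode.value == "known"
        assert azero.cov_mode.value == "assumed_zero"
        assert known.value != pytest.approx(azero.value, rel=1e-6)

    def test_strong_identification_rejects_for_both_exposures(self, both_identified_summary):
        crit = stats.chi2.ppf(0.95, both_identified_summary.L - 1)
        assert q_strength(both_identified_summary, 0).value > crit
        assert q_strength(both_identified_summary, 1).value > crit
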