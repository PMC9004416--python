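import numpy as np
import pandas as pd
import pytest
from scipy import stats

from canalyzer import (SimulationConfig, adjust_covariates,
                       continuous_canalization, interaction_regression,
                       inverse_normal_transform,
                       matched_prevalence_threshold,
                       simulate_continuous_cohort)
from canalyzer.simulate import COVARIATE_NAMES


def _cohort_with(trait, pgs=None, env=None, **cov_overrides):
    n = len(trait)
    rng = np.random.default_rng(0)
    data = {
        "individual_id": [f"i{k}" for k in range(n)],
        "pgs": rng.normal(size=n) if pgs is None else np.asarray(pgs, float),
        "trait": np.asarray(trait, float),
        "env": rng.integers(0, 2, n) if env is None
               else np.asarray(env, int),
    }
    for c in COVARIATE_NAMES:
        data[c] = cov_overrides.get(c, rng.normal(size=n))
    return pd.DataFrame(data)


class TestAdjustCovariates:
    def test_zero_effects_leave_trait_unchanged_up_to_noise(self):
        rng = np.random.default_rng(1)
        trait = rng.normal(size=20_000)
        cohort = _cohort_with(trait)
        adjusted = adjust_covariates(cohort)
        assert np.corrcoef(adjusted, trait)[0, 1] > 0.999

    def test_residual_orthogonal_to_covariate(self):
        rng = np.random.default_rng(2)
        n = 100_000
        age = rng.normal(55, 8, n)
        trait = 2.0 * age + rng.normal(0, 1, n)
        cohort = _cohort_with(trait, age=age)
        adjusted = adjust_covariates(cohort)
        assert abs(np.corrcoef(adjusted, age)[0, 1]) < 0.01

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(3)
        trait = 3 + rng.normal(size=5000)
        cohort = _cohort_with(trait)
        adjusted = adjust_covariates(cohort)
        assert adjusted.mean() == pytest.approx(trait.mean(), abs=1e-10)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=1000)
        cohort = _cohort_with(rng.normal(size=1000), pc1=x, pc2=x)
        with pytest.raises(ValueError, match="collinear"):
            adjust_covariates(cohort)


class TestInverseNormalTransform:
    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(size=1000)
        np.testing.assert_allclose(inverse_normal_transform(x),
                                   inverse_normal_transform(np.log(x)),
                                   atol=1e-12)

    def test_median_of_three_maps_to_zero(self):
        out = inverse_normal_transform(np.array([5.0, 1.0, 9.0]))
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_removes_skew(self):
        rng = np.random.default_rng(6)
        z = inverse_normal_transform(rng.lognormal(sigma=1.5, size=10_000))
        assert abs(stats.skew(z)) < 0.02
        assert abs(z.mean()) < 0.01
        assert abs(z.std() - 1) < 0.01

    def test_idempotent_up_to_rank(self):
        rng = np.random.default_rng(7)
        z = inverse_normal_transform(rng.exponential(size=500))
        z2 = inverse_normal_transform(z)
        assert np.corrcoef(z, z2)[0, 1] > 1 - 1e-10

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(np.ones(10))


class TestInteractionRegression:
    def _generate(self, gamma, n=100_000, seed=8):
        rng = np.random.default_rng(seed)
        pgs = rng.normal(size=n)
        env = rng.integers(0, 2, n)
        trait = (0.5 * pgs + 0.3 * env + gamma * pgs * env
                 + rng.normal(0, 1, n))
        return _cohort_with(trait, pgs=pgs, env=env)

    def test_gamma_recovered(self):
        fits = interaction_regression(self._generate(0.2))
        assert fits["raw"].gamma == pytest.approx(0.2, abs=0.02)

    def test_null_gamma_within_two_se(self):
        fit = interaction_regression(self._generate(0.0))["raw"]
        assert abs(fit.gamma) < 2.5 * fit.bse["gamma"]

    def test_int_scale_fit_reported(self):
        fits = interaction_regression(self._generate(0.2, n=20_000))
        assert fits["int"].scale == "int"
        assert fits["int"].gamma > 0

    def test_constant_env_rejected(self):
        cohort = self._generate(0.0, n=1000)
        with pytest.raises(ValueError):
            interaction_regression(cohort.assign(env=0))


class TestContinuousCanalization:
    def test_null_labelled_none(self, null_continuous_cohort):
        res = continuous_canalization(null_continuous_cohort, n_perm=100,
                                      seed=9)
        assert res.label == "none"
        assert (res.perm_deltas.min() <= res.delta_obs_int
                <= res.perm_deltas.max())

    def test_cf_amplification_is_decanalization(self, cf_amplified_cohort):
        res = continuous_canalization(cf_amplified_cohort, n_perm=100,
                                      seed=10)
        assert res.label == "decanalization"
        assert res.var_high > res.var_low

    def test_delta_and_variance_criteria_agree_in_sign(
            self, cf_amplified_cohort):
        res = continuous_canalization(cf_amplified_cohort, n_perm=20,
                                      seed=11)
        assert np.sign(res.delta_obs_int) == np.sign(
            res.var_high - res.var_low)

    def test_modest_sp_shift_is_not_interaction(self):
        cfg = SimulationConfig(n=20_000, sp_high=15.5, resid_sd=2.0,
                               seed=106)
        cohort = simulate_continuous_cohort(cfg)
        res = continuous_canalization(cohort, n_perm=100, seed=12)
        assert res.label != "decanalization"

    def test_deterministic_given_seed(self, cf_amplified_cohort):
        a = continuous_canalization(cf_amplified_cohort, n_perm=5, seed=13)
        b = continuous_canalization(cf_amplified_cohort, n_perm=5, seed=13)
        assert a.delta_obs_int == b.delta_obs_int
        np.testing.assert_array_equal(a.perm_deltas, b.perm_deltas)


class TestMatchedPrevalenceThreshold:
    def test_identical_distributions_identical_cutoffs(self):
        rng = np.random.default_rng(14)
        trait = rng.normal(25, 4, 50_000)
        cohort = _cohort_with(trait)
        cutoffs, _ = matched_prevalence_threshold(cohort, threshold=30.0)
        assert cutoffs[1] == pytest.approx(cutoffs[0], abs=0.2)

    def test_location_shift_moves_cutoff(self):
        rng = np.random.default_rng(15)
        n = 50_000
        env = rng.integers(0, 2, n)
        trait = rng.normal(25, 4, n) + 2.0 * env
        cohort = _cohort_with(trait, env=env)
        cutoffs, _ = matched_prevalence_threshold(
            cohort, threshold=30.0, target_prevalence_from=0)
        assert cutoffs[1] - cutoffs[0] == pytest.approx(2.0, abs=0.25)

    def test_dichotomized_prevalences_match(self):
        rng = np.random.default_rng(16)
        n = 40_000
        env = rng.integers(0, 2, n)
        trait = rng.normal(25, 4, n) + 1.5 * env
        cohort = _cohort_with(trait, env=env)
        _, dichot = matched_prevalence_threshold(cohort, threshold=30.0)
        prev = dichot.groupby("env")["trait"].mean()
        assert abs(prev[1] - prev[0]) < 2.0 / (env == 1).sum() * 100
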