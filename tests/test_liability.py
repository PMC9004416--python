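import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from canalyzer import (LiabilityModel, SimulationConfig, analyze_binary_pair,
                       bin_liabilities, delta_expected, departure_score,
                       expected_prevalence, fit_liability_model,
                       liability_threshold, score_pgs, simulate_genotypes,
                       stratified_effect_sizes)
from canalyzer.curves import build_curve, percentile_bins


class TestLiabilityThreshold:
    def test_half_prevalence_is_zero(self):
        assert liability_threshold(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_matches_root_finding_oracle(self):
        t = liability_threshold(0.1)
        oracle = optimize.brentq(lambda x: stats.norm.cdf(x) - 0.9, -10, 10,
                                 xtol=1e-12)
        assert t == pytest.approx(oracle, abs=1e-10)

    def test_antisymmetry(self):
        assert liability_threshold(0.2) == pytest.approx(
            -liability_threshold(0.8), abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1])
    def test_boundary_rejected(self, p):
        with pytest.raises(ValueError):
            liability_threshold(p)


def _curves_from_mu(a=0.4, b=0.3, c=-0.1, d=0.0, p_overall=0.15,
                    n_bins=100):
    """Percentile curves whose prevalences derive from exactly-linear mu."""
    t = liability_threshold(p_overall)
    mean_pgs = stats.norm.ppf((np.arange(n_bins) + 0.5) / n_bins)
    frames = []
    for env in (0, 1):
        mu = a * mean_pgs + b * env + c + d * mean_pgs * env
        frames.append(pd.DataFrame({
            "bin_index": np.arange(1, n_bins + 1),
            "mean_pgs": mean_pgs,
            "value": stats.norm.sf(t - mu),
            "count": 500,
            "env": env,
        }))
    return frames[1], frames[0], p_overall


class TestBinLiabilities:
    def test_mu_zero_at_overall_prevalence(self):
        high, low, p = _curves_from_mu()
        low.loc[10, "value"] = p
        bins = bin_liabilities(high, low, p)
        row = bins.table[(bins.table["env"] == 0)
                         & (bins.table["bin_index"] == 11)]
        assert row["mu"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_is_identity(self):
        high, low, p = _curves_from_mu()
        bins = bin_liabilities(high, low, p)
        back = stats.norm.sf(bins.threshold - bins.table["mu"].to_numpy())
        np.testing.assert_allclose(
            back, bins.table["observed_prevalence"].to_numpy(), atol=1e-12)

    def test_degenerate_bins_dropped_and_counted(self):
        high, low, p = _curves_from_mu()
        low.loc[0, "value"] = 0.0
        high.loc[99, "value"] = 1.0
        bins = bin_liabilities(high, low, p)
        assert bins.n_dropped == 2
        assert len(bins.table) == 198

    def test_flat_null_simulation_gives_near_zero_mu(self):
        rng = np.random.default_rng(0)
        n = 100_000
        pgs = rng.normal(size=n)
        trait = (rng.random(n) < 0.2).astype(float)
        env = rng.integers(0, 2, n)
        cohort = pd.DataFrame({"pgs": pgs, "trait": trait, "env": env})
        bins_idx = percentile_bins(pgs)
        high = build_curve(cohort, 1, bins_idx)
        low = build_curve(cohort, 0, bins_idx)
        lbins = bin_liabilities(high, low, trait.mean())
        assert abs(lbins.table["mu"].mean()) < 0.02


class TestLiabilityFit:
    def test_exact_linear_system_recovered(self):
        high, low, p = _curves_from_mu(a=0.4, b=0.3, c=-0.1)
        bins = bin_liabilities(high, low, p)
        fit = fit_liability_model(bins)
        assert fit.a == pytest.approx(0.4, abs=1e-10)
        assert fit.b == pytest.approx(0.3, abs=1e-10)
        assert fit.c == pytest.approx(-0.1, abs=1e-10)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert fit.n_points == 200

    def test_interaction_fit_recovers_d(self):
        high, low, p = _curves_from_mu(d=0.15)
        bins = bin_liabilities(high, low, p)
        fit = fit_liability_model(bins, with_interaction=True)
        assert fit.d == pytest.approx(0.15, abs=1e-10)

    def test_interaction_never_increases_residual(self,
                                                  interaction_binary_cohort):
        pair = analyze_binary_pair(interaction_binary_cohort, seed=1)
        assert (pair["fit_interaction"].residual_sd
                <= pair["fit_null"].residual_sd + 1e-12)

    def test_interaction_absorbs_the_deviation(self,
                                               interaction_binary_cohort):
        # with the PGSxE term the expected curves track the observed ones
        pair = analyze_binary_pair(interaction_binary_cohort, seed=1)
        bins = pair["liability_bins"]
        for fit, bound in ((pair["fit_null"], None),
                           (pair["fit_interaction"], 0.02)):
            exp = expected_prevalence(fit, bins)
            gap = np.abs(exp["expected_prevalence"]
                         - exp["observed_prevalence"])
            if bound is not None:
                assert gap.mean() < bound
        null_gap = np.abs(
            expected_prevalence(pair["fit_null"], bins)["expected_prevalence"]
            - bins.table["observed_prevalence"])
        int_gap = np.abs(
            expected_prevalence(pair["fit_interaction"],
                                bins)["expected_prevalence"]
            - bins.table["observed_prevalence"])
        assert int_gap.mean() < null_gap.mean()


class TestExpectedPrevalence:
    def test_saturating_fit_reproduces_observed(self):
        high, low, p = _curves_from_mu(a=0.5, b=0.2, c=0.0)
        bins = bin_liabilities(high, low, p)
        fit = fit_liability_model(bins)
        exp = expected_prevalence(fit, bins)
        np.testing.assert_allclose(exp["expected_prevalence"],
                                   exp["observed_prevalence"], atol=1e-10)


class TestDeltaExpected:
    def _setup(self):
        high, low, p = _curves_from_mu(a=0.5, b=0.3)
        bins = bin_liabilities(high, low, p)
        fit = fit_liability_model(bins)
        return fit, bins

    def test_zero_residual_is_deterministic(self):
        fit, bins = self._setup()
        mean, sd, draws = delta_expected(fit, bins, 0.0, 1.0, n_iter=10,
                                         seed=1)
        assert sd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(draws, draws[0], atol=1e-12)

    def test_deterministic_given_seed(self, interaction_binary_cohort):
        a = analyze_binary_pair(interaction_binary_cohort, seed=7)
        b = analyze_binary_pair(interaction_binary_cohort, seed=7)
        assert a["delta_exp_mean"] == b["delta_exp_mean"]
        assert a["delta_exp_sd"] == b["delta_exp_sd"]

    def test_ten_iterations_consistent_with_many(self,
                                                 interaction_binary_cohort):
        from canalyzer.curves import percentile_bins as pb
        cohort = interaction_binary_cohort
        pgs = cohort["pgs"].to_numpy()
        bins_idx = pb(pgs)
        high = build_curve(cohort, 1, bins_idx)
        low = build_curve(cohort, 0, bins_idx)
        lbins = bin_liabilities(high, low, float(cohort["trait"].mean()))
        fit = fit_liability_model(lbins)
        m10, s10, _ = delta_expected(fit, lbins, pgs.mean(), pgs.std(),
                                     n_iter=10, seed=3)
        m1k, _, _ = delta_expected(fit, lbins, pgs.mean(), pgs.std(),
                                   n_iter=1000, seed=4)
        assert abs(m10 - m1k) < 3 * s10 / np.sqrt(10) + 1e-6


class TestDepartureScore:
    @pytest.mark.parametrize("obs, exp, scale, label", [
        (0.276, 0.149, (0.276 - 0.149) / 3.884, "decanalization"),
        (-0.030, 0.033, (0.030 + 0.033) / 3.615, "canalization"),
        (0.10, 0.05, 0.05, "none"),
        (0.10, 0.03, 0.05, "suggestive_decanalization"),
    ])
    def test_labels(self, obs, exp, scale, label):
        res = departure_score(obs, exp, scale)
        assert res.label == label

    def test_departure_definition(self):
        res = departure_score(0.3, 0.1, 0.05)
        assert res.departure == pytest.approx((0.3 - 0.1) / 0.05)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            departure_score(0.1, 0.0, 0.0)


@pytest.fixture(scope="module")
def liability_panel():
    panel = simulate_genotypes(n=40_000, m=80, maf_range=(0.1, 0.4),
                               effect_sd=0.15, seed=21)
    score = score_pgs(panel)
    z = (score - score.mean()) / score.std()
    rng = np.random.default_rng(42)
    env = rng.integers(0, 2, len(z))
    liab = 0.7 * z + 0.8 * env + rng.normal(0, 1, len(z))
    cases = (liab > np.quantile(liab, 0.85)).astype(int)
    return panel, cases, env


class TestStratifiedEffectSizes:
    def test_null_variant_logor_near_zero(self):
        panel = simulate_genotypes(n=20_000, m=5, effect_sd=0.0, seed=22)
        rng = np.random.default_rng(1)
        cases = (rng.random(20_000) < 0.2).astype(int)
        env = rng.integers(0, 2, 20_000)
        res = stratified_effect_sizes(panel, cases, env)
        assert np.all(np.abs(res["logor_low"]) < 0.15)
        assert np.all(np.abs(res["logor_high"]) < 0.15)

    def test_higher_prevalence_attenuates_or(self, liability_panel):
        panel, cases, env = liability_panel
        res = stratified_effect_sizes(panel, cases, env)
        strong = np.abs(panel.effect_weights) > 0.05
        ratio = (res["logor_high"] / res["logor_low"])[strong]
        assert np.median(ratio[np.isfinite(ratio)]) < 1.0

    def test_cross_stratum_correlation(self, liability_panel):
        panel, cases, env = liability_panel
        res = stratified_effect_sizes(panel, cases, env)
        strong = np.abs(panel.effect_weights) > 0.05
        r = stats.pearsonr(res["logor_low"][strong],
                           res["logor_high"][strong]).statistic
        assert r > 0.5

    def test_missing_cases_rejected(self):
        panel = simulate_genotypes(n=100, m=3, seed=23)
        with pytest.raises(ValueError):
            stratified_effect_sizes(panel, np.zeros(100, dtype=int),
                                    np.random.default_rng(0).integers(
                                        0, 2, 100))
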