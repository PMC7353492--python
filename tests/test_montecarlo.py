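"""Single and nested Monte Carlo shelf-life distributions."""

import numpy as np
import pytest

import frostkin as fk
from frostkin.errors import InvalidInputError, RegionMismatchError
from frostkin.montecarlo import case_study_parameter_distribution


@pytest.fixture(scope="module")
def printed_dist():
    return case_study_parameter_distribution()


class TestSampleParameters:
    def test_zero_sd_collapses_to_means(self, printed_dist, rng):
        pairs = fk.sample_parameters(printed_dist.degenerate(), 50, rng)
        assert np.allclose(pairs[:, 0], printed_dist.mean_k_ref)
        assert np.allclose(pairs[:, 1], printed_dist.mean_E_a)

    def test_sample_means_within_clt_bounds(self, printed_dist):
        n = 100_000
        pairs = fk.sample_parameters(printed_dist, n, np.random.default_rng(7))
        for col, mean, sd in [
            (0, printed_dist.mean_k_ref, printed_dist.sd_k_ref),
            (1, printed_dist.mean_E_a, printed_dist.sd_E_a),
        ]:
            assert abs(pairs[:, col].mean() - mean) < 3 * sd / np.sqrt(n)

    def test_positivity_of_rate_constant_enforced(self):
        dist = fk.ParameterDistribution(1e-4, 1e-3, 1e5, 1e3)
        pairs = fk.sample_parameters(dist, 10_000, np.random.default_rng(0))
        assert np.all(pairs[:, 0] > 0)

    def test_fixed_seed_reproduces_pair_sequence(self, printed_dist):
        a = fk.sample_parameters(printed_dist, 100, np.random.default_rng(3))
        b = fk.sample_parameters(printed_dist, 100, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_discretized_sampling_approximates_the_law(self, printed_dist):
        pairs = fk.sample_parameters(printed_dist, 50_000, np.random.default_rng(1), bins=101)
        assert abs(pairs[:, 1].mean() - printed_dist.mean_E_a) < 5 * printed_dist.sd_E_a / np.sqrt(50_000)
        assert pairs[:, 1].std() == pytest.approx(printed_dist.sd_E_a, rel=0.05)


class TestMcShelfLife:
    def test_degenerate_distribution_reproduces_deterministic_value(self, printed_dist):
        config = fk.MonteCarloConfig(n_iterations=100, seed=0)
        result = fk.mc_shelf_life(printed_dist.degenerate(), -18.0, 0.5, config)
        det = fk.shelf_life_isothermal(fk.ArrheniusParameters(printed_dist.mean_k_ref, printed_dist.mean_E_a), 255.15, 0.5)
        assert np.allclose(result.samples, det)
        assert result.sd < 1e-9

    def test_bit_reproducible_under_fixed_config(self, printed_dist):
        config = fk.MonteCarloConfig(n_iterations=500, seed=11)
        a = fk.mc_shelf_life(printed_dist, -18.0, 0.5, config)
        b = fk.mc_shelf_life(printed_dist, -18.0, 0.5, config)
        assert np.array_equal(a.samples, b.samples)
        assert a.summary() == b.summary()

    def test_region_filtering_narrows_distribution(self, bundle, bundle_region, bundle_param_dist):
        config = fk.MonteCarloConfig(n_iterations=4000, seed=21)
        unfiltered = fk.mc_shelf_life(bundle_param_dist, -18.0, 0.5, config)
        filtered = fk.mc_shelf_life(bundle_param_dist, -18.0, 0.5, config, region=bundle_region)
        assert filtered.variance <= unfiltered.variance
        assert 0.0 < filtered.acceptance_rate <= 1.0

    def test_incompatible_region_raises_diagnostic(self, bundle_region):
        # a parameter law centred far outside the fitted region
        far = fk.ParameterDistribution(0.05, 1e-4, 2.0e5, 100.0)
        config = fk.MonteCarloConfig(n_iterations=50, seed=0)
        with pytest.raises(RegionMismatchError):
            fk.mc_shelf_life(far, -18.0, 0.5, config, region=bundle_region)

    def test_invalid_limit_rejected(self, printed_dist):
        with pytest.raises(InvalidInputError):
            fk.mc_shelf_life(printed_dist, -18.0, 1.5, fk.MonteCarloConfig(n_iterations=10))

    def test_summary_interval_is_empirical_percentile_band(self, printed_dist):
        config = fk.MonteCarloConfig(n_iterations=2000, seed=5)
        result = fk.mc_shelf_life(printed_dist, -18.0, 0.5, config)
        lo, hi = result.interval
        assert lo == pytest.approx(np.percentile(result.samples, 2.5))
        assert hi == pytest.approx(np.percentile(result.samples, 97.5))
        assert lo < result.mean < hi


class TestDoubleMc:
    def test_fully_degenerate_collapses_to_deterministic(self, printed_dist):
        scenario = fk.case_study_scenario()
        config = fk.MonteCarloConfig(n_iterations=50, seed=0)
        result = fk.double_mc_remaining_shelf_life(
            scenario, printed_dist.degenerate(), None, -18.0, 0.5, config, vary_temperatures=False
        )
        params = fk.ArrheniusParameters(printed_dist.mean_k_ref, printed_dist.mean_E_a)
        state = fk.retention_dynamic(params, fk.mean_profile(scenario))
        det = fk.remaining_shelf_life(state, params, 255.15, 0.5)
        assert np.allclose(result.samples, det, rtol=1e-12)

    def test_temperature_only_mode_has_fixed_parameters(self, printed_dist):
        scenario = fk.case_study_scenario()
        config = fk.MonteCarloConfig(n_iterations=300, seed=4)
        result = fk.double_mc_remaining_shelf_life(
            scenario, printed_dist, None, -18.0, 0.5, config, vary_parameters=False
        )
        assert result.sd > 0  # temperature variability alone spreads the outcome

    def test_combined_variance_dominates_each_source(self, printed_dist):
        scenario = fk.case_study_scenario()
        config = fk.MonteCarloConfig(n_iterations=4000, seed=9)
        both = fk.double_mc_remaining_shelf_life(scenario, printed_dist, None, -18.0, 0.5, config)
        p_only = fk.double_mc_remaining_shelf_life(
            scenario, printed_dist, None, -18.0, 0.5, config, vary_temperatures=False
        )
        t_only = fk.double_mc_remaining_shelf_life(
            scenario, printed_dist, None, -18.0, 0.5, config, vary_parameters=False
        )
        assert both.variance >= p_only.variance
        assert both.variance >= t_only.variance

    def test_common_seed_shares_temperature_histories(self, printed_dist):
        """Paired arms with the same seed consume identical temperature draws."""
        scenario = fk.case_study_scenario()
        config = fk.MonteCarloConfig(n_iterations=200, seed=13)
        t_only_a = fk.double_mc_remaining_shelf_life(
            scenario, printed_dist, None, -18.0, 0.5, config, vary_parameters=False
        )
        t_only_b = fk.double_mc_remaining_shelf_life(
            scenario, printed_dist.scaled(2.0), None, -18.0, 0.5, config, vary_parameters=False
        )
        # parameters pinned at identical means → identical outcomes
        assert np.array_equal(t_only_a.samples, t_only_b.samples)

    def test_fraction_expired_counts_negative_remaining_life(self, printed_dist):
        scenario = fk.case_study_scenario()
        config = fk.MonteCarloConfig(n_iterations=2000, seed=2)
        result = fk.double_mc_remaining_shelf_life(scenario, printed_dist, None, -18.0, 0.5, config)
        assert result.fraction_expired == pytest.approx(np.mean(result.samples <= 0))


class TestSensitivity:
    def test_unit_scale_gives_identical_distributions(self, printed_dist):
        scenario = fk.case_study_scenario()
        config = fk.MonteCarloConfig(n_iterations=500, seed=17)
        res = fk.sensitivity_ci_width(printed_dist, 1.0, scenario, None, -18.0, 0.5, config)
        assert np.array_equal(res.base.samples, res.variant.samples)
        assert res.variance_ratio == pytest.approx(1.0)

    def test_tripled_ci_width_inflates_parameter_contribution(self, printed_dist):
        scenario = fk.case_study_scenario()
        config = fk.MonteCarloConfig(n_iterations=3000, seed=17)
        res = fk.sensitivity_ci_width(
            printed_dist, 3.0, scenario, None, -18.0, 0.5, config, vary_temperatures=False
        )
        assert res.variance_ratio > 1.0

    def test_shrunk_ci_width_makes_parameter_error_negligible(self, printed_dist):
        scenario = fk.case_study_scenario()
        config = fk.MonteCarloConfig(n_iterations=3000, seed=17)
        res = fk.sensitivity_ci_width(
            printed_dist, 0.1, scenario, None, -18.0, 0.5, config, vary_temperatures=False
        )
        t_only = fk.double_mc_remaining_shelf_life(
            scenario, printed_dist, None, -18.0, 0.5, config, vary_parameters=False
        )
        assert res.variant.variance < 0.05 * t_only.variance

    def test_identical_replacement_changes_nothing(self, printed_dist):
        scenario = fk.case_study_scenario()
        config = fk.MonteCarloConfig(n_iterations=500, seed=23)
        res = fk.sensitivity_stage_distribution(
            scenario, "domestic", scenario.stages[2].distribution, printed_dist, None, -18.0, 0.5, config
        )
        assert np.array_equal(res.base.samples, res.variant.samples)

    def test_colder_narrower_domestic_freezer_improves_outcome(self, printed_dist):
        scenario = fk.case_study_scenario()
        config = fk.MonteCarloConfig(n_iterations=4000, seed=23)
        better = fk.TruncatedNormal(-18.0, 1.0, -30.0, -2.0)
        res = fk.sensitivity_stage_distribution(
            scenario, "domestic", better, printed_dist, None, -18.0, 0.5, config
        )
        assert res.variant.mean > res.base.mean
        assert res.variant.sd < res.base.sd
        assert res.variant.fraction_expired <= res.base.fraction_expired

    def test_degenerate_stage_replacement_strictly_reduces_variance(self, printed_dist):
        scenario = fk.case_study_scenario()
        config = fk.MonteCarloConfig(n_iterations=3000, seed=29)
        frozen_at_mean = fk.TruncatedNormal(
            scenario.stages[2].distribution.mean(), 1e-9, -30.0, -2.0
        )
        res = fk.sensitivity_stage_distribution(
            scenario, "domestic", frozen_at_mean, printed_dist, None, -18.0, 0.5, config
        )
        assert res.variant.variance < res.base.variance
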