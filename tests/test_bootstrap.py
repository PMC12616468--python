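"""Replicate-weighted bootstrap: resampling, CI, p-value, power."""

import numpy as np
import pytest

from co2ionome.bootstrap import (
    BootstrapConfig,
    analyze_group,
    bootstrap_p_value,
    bootstrap_power,
    classify_power,
    derive_group_seed,
    percentile_ci,
    weighted_resample_means,
)
from co2ionome.partitioning import GroupKey
from tests.oracles import (
    enumerate_resample_distribution,
    exact_mean_sd,
    quantile_bracket,
)


class TestWeightedResampleMeans:
    def test_constant_sample_gives_constant_means(self):
        means = weighted_resample_means([4.0] * 6, [1, 2, 3, 1, 2, 3],
                                        500, seed=1)
        assert np.all(means == 4.0)

    def test_same_seed_reproduces(self):
        args = ([0.1, -0.2, 0.5], [1, 2, 3], 200)
        a = weighted_resample_means(*args, seed=42)
        b = weighted_resample_means(*args, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_mean_of_means_approaches_weighted_mean(self):
        """{0,1,2} with weights {1,1,2}: enumeration gives E[mean] = 1.25."""
        values, weights = [0.0, 1.0, 2.0], [1.0, 1.0, 2.0]
        atoms, probs = enumerate_resample_distribution(values, weights)
        exact_mean, exact_sd = exact_mean_sd(atoms, probs)
        assert exact_mean == pytest.approx(1.25, abs=1e-12)
        B = 40_000
        means = weighted_resample_means(values, weights, B, seed=7)
        assert means.mean() == pytest.approx(
            exact_mean, abs=3 * exact_sd / np.sqrt(B))

    def test_empty_values_error(self):
        with pytest.raises(ValueError):
            weighted_resample_means([], [], 10, seed=0)

    def test_nonpositive_weight_error(self):
        with pytest.raises(ValueError):
            weighted_resample_means([1.0, 2.0], [1.0, 0.0], 10, seed=0)


class TestPercentileCI:
    def test_constant_distribution(self):
        assert percentile_ci([3.0] * 50) == (3.0, 3.0)

    def test_order_statistic_interpolation(self):
        lo, hi = percentile_ci(np.arange(1, 1001, dtype=float), alpha=0.05)
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_symmetric_distribution_gives_symmetric_interval(self):
        means = np.concatenate([np.linspace(-1, 1, 999), [0.0]]) + 5.0
        lo, hi = percentile_ci(means)
        assert (lo - 5.0) == pytest.approx(-(hi - 5.0), abs=1e-9)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            percentile_ci([])


class TestPValue:
    def test_null_sample_gives_large_p(self, rng):
        values = rng.normal(0.0, 1.0, 400)
        values -= values.mean()  # exactly centered null
        cfg = BootstrapConfig(n_resamples=4000, seed=5)
        p = bootstrap_p_value(values, np.ones(400), cfg)
        assert p > 0.5

    def test_zero_spread_nonzero_mean_gives_p_zero(self):
        cfg = BootstrapConfig(n_resamples=100, seed=0)
        assert bootstrap_p_value([5.0] * 4, [1] * 4, cfg) == 0.0

    def test_zero_spread_zero_mean_gives_p_one(self):
        cfg = BootstrapConfig(n_resamples=100, seed=0)
        assert bootstrap_p_value([0.0] * 4, [1] * 4, cfg) == 1.0

    def test_overwhelming_signal(self, rng):
        # mean ten standard errors from zero
        values = rng.normal(1.0, 1.0, 100) * 0.1 + 1.0
        cfg = BootstrapConfig(n_resamples=4000, seed=9)
        p = bootstrap_p_value(values, np.ones(100), cfg)
        assert p < 0.001


class TestPower:
    def test_vanishing_shift_gives_alpha(self, rng):
        """With no real shift, ~alpha of resample means leave the CI."""
        values = rng.normal(-0.03, 0.1, 100)
        weights = np.ones(100)
        cfg = BootstrapConfig(n_resamples=8000, power_effect=1e-12, seed=11)
        means = weighted_resample_means(values, weights, cfg.n_resamples,
                                        np.random.default_rng(21))
        ci = percentile_ci(means, cfg.alpha)
        power, floored = bootstrap_power(values, weights, cfg, ci,
                                         rng=np.random.default_rng(22))
        assert not floored
        assert power == pytest.approx(cfg.alpha, abs=0.03)

    def test_large_sample_small_spread_gives_power_one(self, rng):
        shift = abs(np.log1p(-0.05))
        values = rng.normal(0.0, shift / 10, 200)
        weights = np.ones(200)
        cfg = BootstrapConfig(n_resamples=2000, seed=3)
        means = weighted_resample_means(values, weights, cfg.n_resamples,
                                        np.random.default_rng(31))
        ci = percentile_ci(means, cfg.alpha)
        power, _ = bootstrap_power(values, weights, cfg, ci,
                                   rng=np.random.default_rng(32))
        assert power > 0.99

    def test_sd_floor_is_conservative(self, rng):
        """Inflating a tiny sample's spread to the dataset SD moves mass
        back toward the interval: floored power never exceeds unfloored."""
        values = rng.normal(0.0, 0.01, 5)
        weights = np.ones(5)
        cfg_floor = BootstrapConfig(n_resamples=4000, seed=17,
                                    small_sample_threshold=20)
        cfg_plain = BootstrapConfig(n_resamples=4000, seed=17,
                                    small_sample_threshold=2)
        means = weighted_resample_means(values, weights, 4000,
                                        np.random.default_rng(41))
        ci = percentile_ci(means)
        p_floor, floored = bootstrap_power(
            values, weights, cfg_floor, ci, dataset_sd=0.2,
            rng=np.random.default_rng(42))
        p_plain, unfloored = bootstrap_power(
            values, weights, cfg_plain, ci, dataset_sd=0.2,
            rng=np.random.default_rng(42))
        assert floored and not unfloored
        assert p_floor <= p_plain

    def test_missing_dataset_sd_for_small_group_errors(self):
        cfg = BootstrapConfig(n_resamples=100, seed=0)
        with pytest.raises(ValueError, match="dataset_sd"):
            bootstrap_power([0.1, 0.2, 0.3], [1, 1, 1], cfg, (0.0, 0.3))

    def test_power_monotone_in_shift(self, rng):
        values = rng.normal(0.0, 0.2, 50)
        weights = np.ones(50)
        means = weighted_resample_means(values, weights, 4000,
                                        np.random.default_rng(51))
        ci = percentile_ci(means)
        powers = []
        for effect in (0.02, 0.05, 0.10, 0.20):
            cfg = BootstrapConfig(n_resamples=4000, power_effect=effect,
                                  seed=0)
            power, _ = bootstrap_power(values, weights, cfg, ci,
                                       rng=np.random.default_rng(52))
            powers.append(power)
        assert all(b >= a - 0.01 for a, b in zip(powers, powers[1:]))

    def test_power_monotone_in_group_size(self, rng):
        pool = rng.normal(0.0, 0.2, 200)
        powers = []
        for n in (20, 50, 200):
            values, weights = pool[:n], np.ones(n)
            means = weighted_resample_means(values, weights, 4000,
                                            np.random.default_rng(61))
            ci = percentile_ci(means)
            cfg = BootstrapConfig(n_resamples=4000, seed=0)
            power, _ = bootstrap_power(values, weights, cfg, ci,
                                       rng=np.random.default_rng(62))
            powers.append(power)
        assert all(b >= a - 0.02 for a, b in zip(powers, powers[1:]))


class TestClassifyPower:
    @pytest.mark.parametrize("power,label", [
        (0.0, "low"), (0.3, "low"), (0.39999, "low"),
        (0.4, "medium"), (0.6, "medium"), (0.8, "medium"),
        (0.80001, "high"), (0.9, "high"), (1.0, "high"),
    ])
    def test_rubric(self, power, label):
        assert classify_power(power) == label

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            classify_power(1.2)


class TestAnalyzeGroup:
    KEY = GroupKey(levels=(("nutrient", "Zn"),))

    def test_constant_group(self):
        cfg = BootstrapConfig(n_resamples=500, seed=1)
        res = analyze_group(self.KEY, [np.log(0.9)] * 8, [2] * 8, cfg,
                            dataset_sd=0.1)
        assert res.mean_pct == pytest.approx(-10.0, abs=1e-9)
        assert res.ci_low_pct == pytest.approx(-10.0, abs=1e-9)
        assert res.ci_high_pct == pytest.approx(-10.0, abs=1e-9)
        assert res.p_value == 0.0 and res.significant
        assert res.direction == "decrease"
        assert res.n_obs_pairs == 16

    def test_bit_identical_given_same_seed(self, rng):
        values = rng.normal(-0.05, 0.1, 30)
        weights = rng.integers(1, 8, 30)
        cfg = BootstrapConfig(n_resamples=1000, seed=99)
        a = analyze_group(self.KEY, values, weights, cfg, dataset_sd=0.1)
        b = analyze_group(self.KEY, values, weights, cfg, dataset_sd=0.1)
        assert a == b

    def test_seed_independent_of_iteration_order(self):
        other = GroupKey(levels=(("nutrient", "Fe"),))
        assert derive_group_seed(1, self.KEY) != derive_group_seed(1, other)
        assert derive_group_seed(1, self.KEY) == derive_group_seed(1, self.KEY)
        assert 0 <= derive_group_seed(1, self.KEY) < 2**31

    def test_single_entry_group_uses_floor(self):
        cfg = BootstrapConfig(n_resamples=500, seed=5)
        res = analyze_group(self.KEY, [np.log(0.95)], [3], cfg,
                            dataset_sd=0.1)
        assert res.n_entries == 1
        assert res.sd_floor_applied
        assert 0.0 <= res.power <= 1.0

    def test_ci_brackets_mean(self, rng):
        values = rng.normal(-0.05, 0.1, 40)
        cfg = BootstrapConfig(n_resamples=2000, seed=2)
        res = analyze_group(self.KEY, values, np.ones(40), cfg,
                            dataset_sd=0.1)
        assert res.ci_low_pct <= res.mean_pct <= res.ci_high_pct


class TestEnumerationOracle:
    def test_three_value_groups_match_exact_enumeration(self):
        """Monte-Carlo mean and CI versus the exact 27-outcome weighted
        distribution, across randomized tiny samples."""
        B = 10_000
        for case in range(25):
            rng = np.random.default_rng(1000 + case)
            values = rng.normal(0.0, 1.0, 3)
            weights = rng.integers(1, 6, 3).astype(float)
            atoms, probs = enumerate_resample_distribution(values, weights)
            exact_mean, exact_sd = exact_mean_sd(atoms, probs)
            means = weighted_resample_means(values, weights, B,
                                            seed=2000 + case)
            assert means.mean() == pytest.approx(
                exact_mean, abs=3 * exact_sd / np.sqrt(B))
            lo, hi = percentile_ci(means)
            for level, got in ((0.025, lo), (0.975, hi)):
                slack = 3 * np.sqrt(level * (1 - level) / B) + 1.0 / B
                blo, bhi = quantile_bracket(atoms, probs, level, slack)
                assert blo - 1e-12 <= got <= bhi + 1e-12
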