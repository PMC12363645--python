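"""Bootstrapped CIs, significance maps and the consecutive threshold."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periboot import (
    BootstrapConfig,
    DesignError,
    GroupMatrix,
    SignificanceMap,
    adjusted_percentile_ci,
    apply_consecutive_threshold,
    baseline_significance,
    between_group_difference,
    bootstrap_mean_samples,
    recommend_consecutive_threshold,
    significant_rows,
    within_group_difference,
)


class TestBootstrapMeanSamples:
    def test_single_column_reproduces_trace(self):
        trace = np.array([[1.0], [2.0], [3.0]])
        boot = bootstrap_mean_samples(trace, 20, rng=0)
        assert boot.shape == (20, 3)
        assert np.array_equal(boot, np.tile(trace.ravel(), (20, 1)))

    def test_constant_matrix_gives_constant_means(self):
        boot = bootstrap_mean_samples(np.full((5, 4), 2.5), 50, rng=1)
        assert np.all(boot == 2.5)

    def test_two_value_enumeration_frequencies(self):
        # T=1, n=2, values {0, 10}: the 4 equally likely draws give means
        # {0, 5, 10} with probabilities {1/4, 1/2, 1/4}
        boot = bootstrap_mean_samples(np.array([[0.0, 10.0]]), 40_000, rng=2).ravel()
        freqs = {v: np.mean(boot == v) for v in (0.0, 5.0, 10.0)}
        assert sum(freqs.values()) == 1.0
        assert freqs[0.0] == pytest.approx(0.25, abs=0.01)
        assert freqs[5.0] == pytest.approx(0.50, abs=0.01)
        assert freqs[10.0] == pytest.approx(0.25, abs=0.01)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean_samples(np.empty((0, 0)), 10, rng=0)


class TestAdjustedPercentileCI:
    def test_degenerate_distribution_gives_point_interval(self):
        low, high = adjusted_percentile_ci(np.full(100, 3.7), 0.95, n=5)
        assert low == high == 3.7

    def test_uniform_grid_matches_hand_computation(self):
        # independent oracle: samples 0..100, level 0.95, n=2.
        # linear-interpolation quantiles are 2.5 and 97.5, the bootstrap
        # mean is 50, and the sqrt(2) widening gives 50 -/+ 47.5*sqrt(2).
        samples = np.arange(101, dtype=float)
        low, high = adjusted_percentile_ci(samples, 0.95, n=2)
        expected_half = 47.5 * math.sqrt(2)
        assert low == pytest.approx(50 - expected_half, abs=1e-9)
        assert high == pytest.approx(50 + expected_half, abs=1e-9)

    def test_large_n_limit_is_raw_percentile_interval(self):
        samples = np.random.default_rng(0).normal(size=1000)
        low, high = adjusted_percentile_ci(samples, 0.95, n=10**9)
        q_low, q_high = np.quantile(samples, [0.025, 0.975])
        assert low == pytest.approx(q_low, abs=1e-6)
        assert high == pytest.approx(q_high, abs=1e-6)

    def test_n_one_returns_unwidened_interval(self):
        samples = np.arange(101, dtype=float)
        low, high = adjusted_percentile_ci(samples, 0.95, n=1)
        assert (low, high) == (2.5, 97.5)

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            adjusted_percentile_ci(np.ones(10), 1.5, n=3)

    def test_matrix_form_matches_columnwise(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(size=(500, 4))
        low, high = adjusted_percentile_ci(samples, 0.95, n=6)
        for t in range(4):
            lo_t, hi_t = adjusted_percentile_ci(samples[:, t], 0.95, n=6)
            assert low[t] == pytest.approx(float(lo_t))
            assert high[t] == pytest.approx(float(hi_t))


class TestSignificanceAgainstBaseline:
    def test_all_zero_data_is_never_significant(self):
        group = GroupMatrix("g", np.zeros((10, 6)))
        ci, sig = baseline_significance(group, BootstrapConfig(n_resamples=200, seed=0))
        assert np.all(ci.lower == 0) and np.all(ci.upper == 0)
        assert not sig.flags.any()

    def test_constant_positive_data_is_significant(self):
        group = GroupMatrix("g", np.full((8, 5), 5.0))
        ci, sig = baseline_significance(group, BootstrapConfig(n_resamples=200, seed=0))
        assert np.all(ci.lower == 5.0) and np.all(ci.upper == 5.0)
        assert sig.flags.all()


class TestBetweenGroupDifference:
    def test_identical_constant_groups_not_significant(self):
        g = GroupMatrix("a", np.full((12, 4), 1.0))
        h = GroupMatrix("b", np.full((12, 4), 1.0))
        ci, sig = between_group_difference(g, h, BootstrapConfig(n_resamples=100, seed=0))
        assert np.all(ci.lower == 0) and np.all(ci.upper == 0)
        assert not sig.flags.any()

    def test_constant_offset_detected_everywhere(self):
        base = np.tile(np.linspace(-1, 1, 12)[:, None], (1, 4))
        g = GroupMatrix("a", base + 10.0)
        h = GroupMatrix("b", base)
        ci, sig = between_group_difference(g, h, BootstrapConfig(n_resamples=100, seed=0))
        assert np.allclose(ci.lower, 10.0) and np.allclose(ci.upper, 10.0)
        assert sig.flags.all()

    def test_unequal_columns_allowed(self):
        rng = np.random.default_rng(0)
        g = GroupMatrix("a", rng.normal(size=(10, 7)))
        h = GroupMatrix("b", rng.normal(size=(10, 5)))
        ci, sig = between_group_difference(g, h, BootstrapConfig(n_resamples=100, seed=0))
        assert len(ci) == 10


class TestWithinGroupDifference:
    def test_identical_groups_never_significant(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(15, 6))
        g = GroupMatrix("a", values)
        h = GroupMatrix("b", values.copy())
        _, sig = within_group_difference(g, h, BootstrapConfig(n_resamples=200, seed=0))
        assert not sig.flags.any()

    def test_swap_antisymmetry_with_shared_draws(self):
        rng = np.random.default_rng(2)
        g = GroupMatrix("a", rng.normal(size=(20, 7)))
        h = GroupMatrix("b", rng.normal(size=(20, 7)))
        cfg = BootstrapConfig(n_resamples=300, seed=9)
        ci_ab, sig_ab = within_group_difference(g, h, cfg)
        ci_ba, sig_ba = within_group_difference(h, g, cfg)
        assert np.allclose(ci_ab.lower, -ci_ba.upper)
        assert np.allclose(ci_ab.upper, -ci_ba.lower)
        assert np.array_equal(sig_ab.flags, sig_ba.flags)

    def test_strong_paired_effect_flags_everything(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(50, 7))
        g = GroupMatrix("a", base + rng.normal(1.0, 0.1, size=(50, 7)))
        h = GroupMatrix("b", base)
        _, sig = within_group_difference(g, h, BootstrapConfig(n_resamples=500, seed=4))
        assert sig.flags.mean() > 0.99

    def test_unequal_columns_is_design_error(self):
        g = GroupMatrix("a", np.ones((5, 7)))
        h = GroupMatrix("b", np.ones((5, 6)))
        with pytest.raises(DesignError, match="between-groups"):
            within_group_difference(g, h, BootstrapConfig(seed=0))


class TestConsecutiveThreshold:
    @pytest.mark.parametrize(
        "flags, k, expected",
        [
            ([1, 1, 0, 1], 2, [1, 1, 0, 0]),
            ([0, 1, 1, 1, 0, 1, 1], 3, [0, 1, 1, 1, 0, 0, 0]),
            ([1, 0, 1], 1, [1, 0, 1]),
            ([1, 1, 1], 0, [1, 1, 1]),
            ([0, 0, 0], 5, [0, 0, 0]),
            ([1, 1, 1, 1, 1], 5, [1, 1, 1, 1, 1]),
        ],
    )
    def test_run_length_rule(self, flags, k, expected):
        out = apply_consecutive_threshold(SignificanceMap(np.array(flags)), k)
        assert out.flags.tolist() == expected

    @given(
        flags=st.lists(st.integers(0, 1), min_size=1, max_size=60),
        k1=st.integers(0, 8),
        k2=st.integers(0, 8),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_idempotent(self, flags, k1, k2):
        m = SignificanceMap(np.array(flags))
        lo, hi = sorted((k1, k2))
        out_lo = apply_consecutive_threshold(m, lo)
        out_hi = apply_consecutive_threshold(m, hi)
        assert np.all(out_hi.flags <= out_lo.flags)
        again = apply_consecutive_threshold(out_hi, hi)
        assert np.array_equal(again.flags, out_hi.flags)


class TestConfidenceNesting:
    def test_99_interval_contains_95_with_shared_draws(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(200, 7))
        boot = bootstrap_mean_samples(values, 1000, rng=np.random.default_rng(6))
        lo95, hi95 = adjusted_percentile_ci(boot, 0.95, n=7)
        lo99, hi99 = adjusted_percentile_ci(boot, 0.99, n=7)
        assert np.all(lo99 <= lo95) and np.all(hi95 <= hi99)
        map95 = (lo95 > 0) | (hi95 < 0)
        map99 = (lo99 > 0) | (hi99 < 0)
        assert np.all(map99 <= map95)


class TestRecommendThreshold:
    def test_sensor_kinetics_rule(self):
        # 0.08 s rise + 0.33 s half-decay at 10 Hz -> 0.41 s -> 4 samples
        assert recommend_consecutive_threshold(0.08, 0.33, 10.0) == 4

    def test_low_pass_rule(self):
        # 6 Hz low-pass at 10 Hz -> 1/6 s -> 2 samples
        assert recommend_consecutive_threshold(0.0, 0.0, 10.0, low_pass_hz=6.0) == 2

    def test_most_conservative_constraint_wins(self):
        # kinetics 0.41 s vs user minimum 0.5 s -> 5 samples at 10 Hz
        assert (
            recommend_consecutive_threshold(0.08, 0.33, 10.0, user_min_s=0.5) == 5
        )

    def test_zero_constraints_floor_at_one_sample(self):
        assert recommend_consecutive_threshold(0.0, 0.0, 10.0) == 1

    def test_sampling_rate_scales_threshold(self):
        assert recommend_consecutive_threshold(0.08, 0.33, 1.0) == 1
        assert recommend_consecutive_threshold(0.08, 0.33, 100.0) == 41

    def test_nonpositive_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            recommend_consecutive_threshold(0.1, 0.1, 0.0)


class TestSignificantRows:
    @pytest.mark.parametrize(
        "flags, expected",
        [([0, 1, 1, 0], [1, 2]), ([0, 0, 0], []), ([1, 1, 1], [0, 1, 2])],
    )
    def test_indices(self, flags, expected):
        assert significant_rows(SignificanceMap(np.array(flags))) == expected


def test_identical_seed_gives_identical_results():
    rng = np.random.default_rng(8)
    g = GroupMatrix("a", rng.normal(size=(30, 7)))
    cfg = BootstrapConfig(n_resamples=400, seed=123)
    ci1, sig1 = baseline_significance(g, cfg)
    ci2, sig2 = baseline_significance(g, cfg)
    assert np.array_equal(ci1.lower, ci2.lower)
    assert np.array_equal(ci1.upper, ci2.upper)
    assert np.array_equal(sig1.flags, sig2.flags)
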