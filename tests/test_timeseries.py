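import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.tsa.stattools import acf as sm_acf

from fmpy import (
    AgentSpec,
    BartlettGroups,
    STEP_CODE,
    StepSeries,
    TurnSequence,
    ValidationError,
    acf,
    apply_missing_rule,
    bartlett_statistic,
    confidence_band,
    cumulative_sum,
    encode_steps,
    mirror,
    significant_lags,
    simulate_turns,
    turn_sequence_from_string,
)
from fmpy.tetragram import ALL_TETRAGRAMS
from fmpy.timeseries import CODE_TO_TETRAGRAM

# Signed step length of each tetragram: left-dominant negative, alternations
# at ±1, repetitions at ±8.
EXPECTED_STEP_CODE = {
    "LLLL": -8, "LLLR": -7, "LLRL": -6, "LRLL": -5,
    "RLLL": -4, "LLRR": -3, "LRRL": -2, "LRLR": -1,
    "RLRL": 1, "RLLR": 2, "RRLL": 3, "LRRR": 4,
    "RLRR": 5, "RRLR": 6, "RRRL": 7, "RRRR": 8,
}


class TestStepCode:
    def test_full_16_entry_map(self):
        assert STEP_CODE == EXPECTED_STEP_CODE

    def test_bijection_onto_signed_range_without_zero(self):
        assert sorted(STEP_CODE.values()) == [v for v in range(-8, 9) if v != 0]
        assert set(STEP_CODE) == set(ALL_TETRAGRAMS)
        assert CODE_TO_TETRAGRAM[-8] == "LLLL" and CODE_TO_TETRAGRAM[8] == "RRRR"

    def test_mirror_antisymmetry_all_16(self):
        swap = str.maketrans("LR", "RL")
        for t, code in STEP_CODE.items():
            assert STEP_CODE[t.translate(swap)] == -code


class TestEncodeSteps:
    def test_repetition_blocks(self):
        seq = turn_sequence_from_string("LLLLRRRR")
        assert list(encode_steps(seq).steps) == [-8, 8]

    def test_alternation_block(self):
        assert list(encode_steps(turn_sequence_from_string("LRLR")).steps) == [-1]

    def test_1000_turns_give_250_steps(self, fair_1000):
        assert encode_steps(fair_1000).n == 250

    def test_max_entries_caps_input(self, fair_1000):
        assert encode_steps(fair_1000, max_entries=100).n == 25

    def test_overlapping_flag_gives_stride_one(self):
        seq = turn_sequence_from_string("LRLRLR")
        assert list(encode_steps(seq, overlapping=True).steps) == [-1, 1, -1]
        assert list(encode_steps(seq).steps) == [-1]

    @given(st.text(alphabet="LR", max_size=200))
    @settings(derandomize=True)
    def test_mirror_negates_steps(self, turns):
        seq = TurnSequence("s", turns)
        a = encode_steps(seq).steps
        b = encode_steps(mirror(seq)).steps
        assert np.array_equal(b, -a)

    @given(st.text(alphabet="LR", max_size=200))
    @settings(derandomize=True)
    def test_block_count(self, turns):
        assert encode_steps(TurnSequence("s", turns)).n == len(turns) // 4


class TestMissingRule:
    def test_small_deficit_zero_filled(self):
        s = StepSeries("z", np.ones(245, dtype=int))
        out = apply_missing_rule(s)
        assert not out.excluded
        assert out.n == 250 and out.n_missing_filled == 5
        assert list(out.steps[-5:]) == [0] * 5

    def test_large_deficit_excluded(self):
        out = apply_missing_rule(StepSeries("z", np.ones(230, dtype=int)))
        assert out.excluded

    def test_exact_length_unchanged(self):
        steps = np.ones(250, dtype=int)
        out = apply_missing_rule(StepSeries("z", steps))
        assert not out.excluded and out.n_missing_filled == 0
        assert np.array_equal(out.steps, steps)

    def test_boundary_exactly_max_missing_is_retained(self):
        out = apply_missing_rule(StepSeries("z", np.ones(240, dtype=int)))
        assert not out.excluded and out.n_missing_filled == 10
        out = apply_missing_rule(StepSeries("z", np.ones(239, dtype=int)))
        assert out.excluded

    def test_surplus_truncated(self):
        out = apply_missing_rule(StepSeries("z", np.ones(300, dtype=int)))
        assert out.n == 250 and out.n_missing_filled == 0

    @given(st.integers(min_value=0, max_value=300))
    @settings(derandomize=True)
    def test_retained_totals(self, n):
        out = apply_missing_rule(StepSeries("z", np.ones(n, dtype=int)))
        if not out.excluded:
            assert (out.n - out.n_missing_filled) + out.n_missing_filled == 250


class TestCumulativeSum:
    def test_arithmetic(self):
        assert list(cumulative_sum(StepSeries("z", [-1, -1, -1]))) == [-1, -2, -3]
        assert list(cumulative_sum(StepSeries("z", [8, -8]))) == [8, 0]
        assert list(cumulative_sum(StepSeries("z", [0, 0]))) == [0, 0]

    def test_excluded_series_rejected(self):
        s = apply_missing_rule(StepSeries("z", np.ones(10, dtype=int)))
        with pytest.raises(ValidationError, match="excluded"):
            cumulative_sum(s)


class TestACF:
    def test_alternating_series_lag1_is_minus_point_nine(self):
        x = np.tile([1.0, -1.0], 5)  # n = 10
        assert acf(x, 1).r[0] == pytest.approx(-0.9)

    def test_matches_textbook_biased_estimator_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=250)
            ours = acf(x, 20).r
            oracle = sm_acf(x, nlags=20, fft=False, adjusted=False)[1:]
            assert np.allclose(ours, oracle, atol=1e-12, rtol=0)

    def test_coefficients_bounded_by_one(self):
        rng = np.random.default_rng(1)
        res = acf(np.cumsum(rng.normal(size=250)), 30)
        assert np.all(np.abs(res.r) <= 1.0)
        assert res.lag(0) == 1.0

    def test_iid_noise_fluctuates_near_zero(self):
        rng = np.random.default_rng(2)
        res = acf(rng.normal(size=250), 20)
        assert np.max(np.abs(res.r)) < 0.25

    def test_constant_series_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            acf(np.ones(50), 5)

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            acf(np.arange(10.0), 9)


class TestConfidenceBands:
    def test_naive_halfwidth_flat_at_0_1240(self):
        rng = np.random.default_rng(3)
        res = confidence_band(acf(rng.normal(size=250), 20), "naive")
        assert np.allclose(res.upper, 1.96 / np.sqrt(250))
        assert res.upper[0] == pytest.approx(0.1240, abs=5e-5)

    def test_large_lag_equals_naive_at_lag_1_then_grows(self):
        rng = np.random.default_rng(4)
        walk = np.cumsum(rng.normal(size=250))
        res = confidence_band(acf(walk, 20), "large_lag_bartlett")
        assert res.upper[0] == pytest.approx(1.96 / np.sqrt(250))
        assert np.all(np.diff(res.upper) >= 0)
        expected_lag2 = 1.96 * np.sqrt((1 + 2 * res.r[0] ** 2) / 250)
        assert res.upper[1] == pytest.approx(expected_lag2)

    def test_printed_bartlett_band_attaches_group_diagnostics(self):
        rng = np.random.default_rng(5)
        walk = np.cumsum(rng.normal(size=250))
        res = confidence_band(acf(walk, 20), "printed_bartlett")
        assert res.bartlett_groups is not None
        assert res.bartlett_groups.k == 10
        assert np.all(res.upper > 0)

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(6)
        res = acf(rng.normal(size=100), 10)
        with pytest.raises(ValidationError, match="unknown band"):
            confidence_band(res, "bogus")


class TestSignificantLags:
    def test_counts_lags_outside_band(self):
        res = acf(np.cumsum(np.random.default_rng(7).normal(size=250)), 20)
        res = confidence_band(res, "naive")
        expected = int(np.sum((res.r < res.lower) | (res.r > res.upper)))
        assert significant_lags(res, 20) == expected

    def test_all_inside_gives_zero(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=2000)
            res = confidence_band(acf(x, 5), "large_lag_bartlett")
            if significant_lags(res, 5) == 0:
                break
        else:
            pytest.fail("no quiet ACF found among white-noise draws")

    def test_band_required(self):
        with pytest.raises(ValidationError, match="band"):
            significant_lags(acf(np.arange(50.0), 5), 5)

    def test_long_memory_signature_of_cumulative_walks(self):
        """Cumulative sums of iid step series: lag-1 ACF near 1 over seeds."""
        r1 = []
        for seed in range(20):
            seq = simulate_turns(AgentSpec("iid", seed=seed), 1000)
            walk = cumulative_sum(apply_missing_rule(encode_steps(seq)))
            r1.append(acf(walk, 1).r[0])
        assert min(r1) > 0.9


class TestBartlettStatistic:
    def test_zero_when_group_variances_equal(self):
        g = BartlettGroups(sizes=[10, 10, 10], variances=[2.0, 2.0, 2.0])
        assert bartlett_statistic(g) == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_against_direct_numeric_oracle(self):
        n1 = n2 = 10
        v1, v2 = 1.0, 4.0
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        num = (n1 + n2 - 2) * np.log(sp2) - ((n1 - 1) * np.log(v1) + (n2 - 1) * np.log(v2))
        den = 1 + (1 / 3) * ((1 / (n1 - 1) + 1 / (n2 - 1)) - 1 / (n1 + n2 - 2))
        g = BartlettGroups(sizes=[n1, n2], variances=[v1, v2])
        assert bartlett_statistic(g) == pytest.approx(num / den)

    def test_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(9)
        samples = [rng.normal(scale=s, size=n) for s, n in [(1, 12), (2, 20), (1.5, 9)]]
        ours = bartlett_statistic(BartlettGroups.from_samples(samples))
        oracle = scipy.stats.bartlett(*samples).statistic
        assert ours == pytest.approx(oracle, rel=1e-12)

    def test_pooled_variance_is_weighted_mean(self):
        g = BartlettGroups(sizes=[5, 15], variances=[1.0, 3.0])
        assert g.pooled_variance == pytest.approx((4 * 1.0 + 14 * 3.0) / 18)

    def test_preconditions(self):
        with pytest.raises(ValidationError, match="2 groups"):
            BartlettGroups(sizes=[10], variances=[1.0])
        with pytest.raises(ValidationError, match="zero-variance"):
            BartlettGroups(sizes=[10, 10], variances=[1.0, 0.0])
        with pytest.raises(ValidationError, match="at least 2 obs"):
            BartlettGroups(sizes=[1, 10], variances=[1.0, 1.0])
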