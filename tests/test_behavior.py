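"""Sleep calling, interval totals, deprivation efficiency, windows and rebound."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepermeta.behavior import (
    ActivityTrace,
    SleepWindows,
    call_sleep,
    cumulative_windows,
    exclude_dead,
    passes_sd_filter,
    rebound_windows,
    sd_efficiency,
    sleep_change,
    total_sleep,
)

from conftest import brute_force_sleep, make_series, make_trace


class TestCallSleep:
    def test_long_zero_run_is_one_bout(self):
        counts = [2] * 5 + [0] * 10 + [3] * 5
        s = make_series(counts)
        assert s.bouts == [(5, 10)]
        assert s.total_minutes == 10

    def test_below_threshold_runs_never_count(self):
        counts = ([1, 0, 0, 0, 0] * 10) + [1]
        s = make_series(counts)
        assert s.total_minutes == 0
        assert s.bouts == []

    def test_nine_minute_run_is_single_bout_not_partitioned(self):
        s = make_series([1] + [0] * 9 + [1])
        assert s.bouts == [(1, 9)]

    def test_custom_min_bout(self):
        tr = make_trace([1, 0, 0, 0, 1])
        assert call_sleep(tr, min_bout_minutes=3).total_minutes == 3
        assert call_sleep(tr, min_bout_minutes=4).total_minutes == 0

    def test_matches_bruteforce_on_random_day_traces(self, rng):
        for _ in range(200):
            counts = rng.integers(0, 2, 1440) * rng.poisson(2, 1440)
            got = make_series(counts).asleep
            assert np.array_equal(got, brute_force_sleep(counts))

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=60))
    def test_matches_bruteforce_property(self, counts):
        assert np.array_equal(make_series(counts).asleep, brute_force_sleep(counts))

    def test_bout_minutes_equal_asleep_minutes(self, rng):
        counts = rng.integers(0, 2, 1440)
        s = make_series(counts)
        assert sum(d for _, d in s.bouts) == s.total_minutes

    @pytest.mark.parametrize(
        "bad", [[], [-1, 0, 0], [0.5, 0.0, 1.0]], ids=["empty", "negative", "fractional"]
    )
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            ActivityTrace(fly_id="f", condition_id="c", counts=np.asarray(bad))


class TestTotalSleep:
    def test_saturated_night(self):
        s = make_series([1] * 720 + [0] * 720)
        assert total_sleep(s, 720, 1440) == 720

    def test_fully_awake_interval(self):
        s = make_series([1] * 1440)
        assert total_sleep(s, 0, 720) == 0

    def test_equals_direct_slice_count(self, rng):
        counts = rng.integers(0, 2, 2880)
        s = make_series(counts)
        for _ in range(20):
            a, b = sorted(rng.integers(0, 2881, 2))
            if a == b:
                continue
            assert total_sleep(s, a, b) == s.asleep[a:b].sum()

    def test_out_of_range_rejected(self):
        s = make_series([0] * 1440)
        with pytest.raises(ValueError):
            total_sleep(s, -1, 100)
        with pytest.raises(ValueError):
            total_sleep(s, 0, 1441)
        with pytest.raises(ValueError):
            total_sleep(s, 100, 100)

    def test_respects_t0_offset(self):
        s = make_series([0] * 1440, t0=240)
        assert total_sleep(s, 240, 300) == 60
        with pytest.raises(ValueError):
            total_sleep(s, 0, 60)


class TestSdEfficiency:
    def _two_day(self, day0_counts, day1_counts):
        return make_series(list(day0_counts) + list(day1_counts))

    def test_full_deprivation_passes(self):
        s = self._two_day([0] * 1440, [1] * 1440)
        eff = sd_efficiency(s, s, (1440 + 720, 2880))
        assert eff == 1.0 and passes_sd_filter(eff)

    def test_exactly_90_percent_fails_strict_filter(self):
        # 300 min baseline sleep, 30 min during SD -> efficiency exactly 0.90
        day0 = [1] * 1140 + [0] * 300
        day1 = [1] * 1410 + [0] * 30
        s = self._two_day(day0, day1)
        eff = sd_efficiency(s, s, (1440 + 1140, 2880))
        assert eff == pytest.approx(0.90)
        assert not passes_sd_filter(eff)

    def test_zero_baseline_cases(self):
        awake = self._two_day([1] * 1440, [1] * 1440)
        assert sd_efficiency(awake, awake, (1440, 2880)) == 1.0
        slept = self._two_day([1] * 1440, [1] * 720 + [0] * 720)
        assert sd_efficiency(slept, slept, (1440, 2880)) == 0.0

    def test_matches_arithmetic_oracle(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 2, 2880)
            s = make_series(counts)
            a, b = 2000, 2600
            sd = s.asleep[a:b].sum()
            base = s.asleep[a - 1440:b - 1440].sum()
            if base == 0:
                continue
            assert sd_efficiency(s, s, (a, b)) == pytest.approx(1 - sd / base)

    def test_depends_only_on_sleep_mask(self, rng):
        counts = rng.integers(0, 2, 2880)
        scaled = counts * rng.integers(1, 50, 2880)
        e1 = sd_efficiency(make_series(counts), make_series(counts), (2000, 2600))
        e2 = sd_efficiency(make_series(scaled), make_series(scaled), (2000, 2600))
        assert e1 == e2


class TestSleepChange:
    def test_identical_days_give_zero(self):
        day = [1] * 720 + [0] * 720
        s = make_series(day * 2)
        assert sleep_change(s, (1440, 2880)) == 0

    def test_activation_gain(self):
        # 100 min sleep on day 0, full 720 min during day-1 "activation"
        day0 = [1] * 620 + [0] * 100 + [1] * 720
        day1 = [0] * 720 + [1] * 720
        s = make_series(day0 + day1)
        assert sleep_change(s, (1440, 2160)) == 620

    def test_equals_two_total_sleep_calls(self, rng):
        counts = rng.integers(0, 2, 2880)
        s = make_series(counts)
        got = sleep_change(s, (1600, 2880))
        assert got == total_sleep(s, 1600, 2880) - total_sleep(s, 160, 1440)

    def test_single_day_recording_rejected(self):
        s = make_series([0] * 1440)
        with pytest.raises(ValueError):
            sleep_change(s, (720, 1440))


class TestCumulativeWindows:
    def test_all_asleep_saturates(self):
        flies = [make_series([0] * 1440) for _ in range(3)]
        w = cumulative_windows(flies, 720, "before")
        assert np.array_equal(w.minutes_asleep, 60 * np.arange(1, 13))

    def test_all_awake_gives_zeros(self):
        flies = [make_series([1] * 1440) for _ in range(2)]
        w = cumulative_windows(flies, 720, "before")
        assert np.array_equal(w.minutes_asleep, np.zeros(12))

    def test_windows_are_nested_totals_and_monotone(self, rng):
        flies = [make_series(rng.integers(0, 2, 2880)) for _ in range(5)]
        w = cumulative_windows(flies, 1440, "before")
        assert (np.diff(w.minutes_asleep) >= 0).all()
        assert (w.minutes_asleep <= 60 * np.arange(1, 13)).all()

    def test_mean_matches_per_fly_oracle(self, rng):
        flies = [make_series(rng.integers(0, 2, 2880)) for _ in range(4)]
        w = cumulative_windows(flies, 1440, "after")
        for i, k in enumerate(range(1, 13)):
            expected = np.mean([f.asleep[1440:1440 + 60 * k].sum() for f in flies])
            assert w.minutes_asleep[i] == pytest.approx(expected)

    def test_noncovering_fly_excluded_from_window_mean(self):
        full = make_series([0] * 2880)
        late = make_series([1] * 1440, t0=1440)  # starts at minute 1440, awake
        w = cumulative_windows([full, late], 1500, "before")
        # 1 h window [1440, 1500) both cover: mean of 60 and 0
        assert w.minutes_asleep[0] == 30 and w.n_flies[0] == 2
        # 2 h window [1380, 1500): only the full fly covers
        assert w.minutes_asleep[1] == 120 and w.n_flies[1] == 1

    def test_no_covering_fly_is_error(self):
        s = make_series([0] * 1440)
        with pytest.raises(ValueError):
            cumulative_windows([s], 300, "before")  # 12 h window starts before 0
        with pytest.raises(ValueError):
            cumulative_windows([], 720, "before")


class TestReboundWindows:
    def _w(self, minutes, direction="after_sampling"):
        k = np.arange(1, 13)
        return SleepWindows("c", direction, k, np.asarray(minutes, float), np.ones(12, int))

    def test_condition_against_itself_is_zero(self):
        w = self._w(60 * np.arange(1, 13))
        r = rebound_windows(w, self._w(60 * np.arange(1, 13), "before_sampling"))
        assert np.array_equal(r.rebound_minutes, np.zeros(12))

    def test_saturated_bounds(self):
        r = rebound_windows(self._w(60 * np.arange(1, 13)), self._w(np.zeros(12)))
        assert np.array_equal(r.rebound_minutes, 60 * np.arange(1, 13))
        assert (np.abs(r.rebound_minutes) <= 60 * np.arange(1, 13)).all()

    def test_elementwise_subtraction(self, rng):
        a = rng.uniform(0, 720, 12)
        b = rng.uniform(0, 720, 12)
        r = rebound_windows(self._w(a), self._w(b))
        assert np.allclose(r.rebound_minutes, a - b)

    def test_direction_and_shape_checked(self):
        with pytest.raises(ValueError):
            rebound_windows(self._w(np.zeros(12), "before_sampling"), self._w(np.zeros(12)))


class TestExcludeDead:
    def test_trailing_quiet_fly_dropped_when_others_active(self):
        alive = make_trace([1] * 2880, fly_id="alive")
        dead = make_trace([1] * 1440 + [0] * 1440, fly_id="dead")
        with pytest.warns(UserWarning):
            kept, dropped = exclude_dead([alive, dead])
        assert dropped == ["dead"]
        assert [t.fly_id for t in kept] == ["alive"]

    def test_everyone_quiet_keeps_all(self):
        t1 = make_trace([1] * 720 + [0] * 720, fly_id="a")
        t2 = make_trace([1] * 720 + [0] * 720, fly_id="b")
        kept, dropped = exclude_dead([t1, t2], min_quiet_hours=12)
        assert dropped == []
        assert len(kept) == 2

    def test_short_quiet_tail_kept(self):
        t1 = make_trace([1] * 2880, fly_id="a")
        t2 = make_trace([1] * 2600 + [0] * 280, fly_id="b")
        kept, dropped = exclude_dead([t1, t2])
        assert dropped == []
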