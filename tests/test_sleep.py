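import math

import numpy as np
import pandas as pd
import pytest

from tubetracker import (
    BinnedCounts,
    PeriodLabel,
    SleepBout,
    average_across_days,
    find_sleep_bouts,
    immobile_minutes,
    sleep_latency,
    sleep_metrics,
    sleep_timecourse,
)
from tubetracker.sleep import per_day_metrics


def counts_from(minute_counts, fly_id="f1", t_start=0):
    arr = np.asarray(minute_counts, dtype=np.int64)
    return BinnedCounts(
        fly_id=fly_id,
        bin_length_s=60,
        t_start=t_start,
        counts=arr,
        valid_bins=np.ones(len(arr), dtype=bool),
    )


def day_from_bouts(bout_specs, background=3):
    """1440-min activity vector: zero runs at (onset, duration), else active."""
    day = np.full(1440, background, dtype=np.int64)
    for onset, dur in bout_specs:
        day[onset : onset + dur] = 0
    return day


class TestImmobileMinutes:
    def test_examples(self):
        assert list(immobile_minutes(counts_from([0, 0, 3]))) == [1, 1, 0]
        assert immobile_minutes(counts_from(np.zeros(1440))).all()

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        c = rng.integers(0, 4, 500)
        imm = immobile_minutes(counts_from(c))
        assert all(imm[i] == (c[i] == 0) for i in range(500))

    def test_wrong_bin_size_rejected(self):
        bad = BinnedCounts("f", 1800, 0, np.zeros(3, int), np.ones(3, bool))
        with pytest.raises(ValueError):
            immobile_minutes(bad)


class TestFindSleepBouts:
    def test_exactly_five_minutes_is_one_bout(self):
        imm = np.r_[np.zeros(3), np.ones(5), np.zeros(3)].astype(int)
        bouts = find_sleep_bouts(imm)
        assert len(bouts) == 1 and bouts[0].duration_min == 5 and bouts[0].onset_min == 3

    def test_four_minutes_is_wake(self):
        imm = np.r_[np.zeros(3), np.ones(4), np.zeros(3)].astype(int)
        assert find_sleep_bouts(imm) == []

    def test_interrupted_run_keeps_only_qualifying_piece(self):
        # 10 immobile minutes split 5 / 4 by one active minute
        imm = np.r_[np.ones(5), [0], np.ones(4)].astype(int)
        bouts = find_sleep_bouts(imm)
        assert [b.duration_min for b in bouts] == [5]

    def test_run_length_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        imm = rng.integers(0, 2, 2000)
        bouts = find_sleep_bouts(imm)
        # brute force: enumerate maximal runs
        runs, i = [], 0
        while i < len(imm):
            if imm[i]:
                j = i
                while j < len(imm) and imm[j]:
                    j += 1
                if j - i >= 5:
                    runs.append((i, j - i))
                i = j
            else:
                i += 1
        assert [(b.onset_min, b.duration_min) for b in bouts] == runs

    def test_bouts_disjoint_and_long_enough(self):
        rng = np.random.default_rng(2)
        bouts = find_sleep_bouts(rng.integers(0, 2, 5000))
        assert all(b.duration_min >= 5 for b in bouts)
        for a, b in zip(bouts, bouts[1:]):
            assert b.onset_min > a.end_min  # separated by >= 1 active minute


class TestSleepMetrics:
    def test_all_day_asleep(self, schedule):
        c = counts_from(np.zeros(1440))
        bouts = find_sleep_bouts(immobile_minutes(c))
        m = sleep_metrics(bouts, c, schedule, PeriodLabel.FULL24)
        assert m.total_sleep_min == 1440
        assert m.episode_count == 1
        assert m.mean_episode_min == m.max_episode_min == 1440
        assert math.isnan(m.activity_while_active)

    def test_never_immobile_five_minutes(self, schedule):
        day = np.tile(np.r_[np.zeros(4), [2]], 288)[:1440].astype(int)
        c = counts_from(day)
        bouts = find_sleep_bouts(immobile_minutes(c))
        m = sleep_metrics(bouts, c, schedule, PeriodLabel.FULL24)
        assert m.total_sleep_min == 0 and m.episode_count == 0

    def test_crafted_dark_period_panel(self, schedule):
        # bouts of 120, 30 and 5 min all with onset in DP
        day = day_from_bouts([(800, 120), (1000, 30), (1200, 5)])
        c = counts_from(day)
        bouts = find_sleep_bouts(immobile_minutes(c))
        m = sleep_metrics(bouts, c, schedule, PeriodLabel.DP)
        assert m.total_sleep_min == 155
        assert m.episode_count == 3
        assert m.mean_episode_min == pytest.approx(155 / 3, abs=0.01)
        assert m.max_episode_min == 120
        # activity while active: 720 DP minutes, 155 asleep, rest at 3 counts
        assert m.activity_while_active == pytest.approx(3.0)

    def test_sleep_plus_wake_partition(self, schedule):
        rng = np.random.default_rng(3)
        day = rng.integers(0, 2, 1440) * rng.integers(0, 5, 1440)
        c = counts_from(day)
        bouts = find_sleep_bouts(immobile_minutes(c))
        for period, length in [
            (PeriodLabel.FULL24, 1440),
            (PeriodLabel.LP, 720),
            (PeriodLabel.DP, 720),
        ]:
            m = sleep_metrics(bouts, c, schedule, period)
            in_period_wake = length - m.total_sleep_min
            assert 0 <= m.total_sleep_min <= length
            assert in_period_wake >= 0
        lp = sleep_metrics(bouts, c, schedule, PeriodLabel.LP)
        dp = sleep_metrics(bouts, c, schedule, PeriodLabel.DP)
        full = sleep_metrics(bouts, c, schedule, PeriodLabel.FULL24)
        assert lp.total_sleep_min + dp.total_sleep_min == full.total_sleep_min

    def test_boundary_spanning_bout_minutes_split_but_counted_at_onset(self, schedule):
        # 20-min bout from ZT 11:50 (min 710) into DP
        day = day_from_bouts([(710, 20)])
        c = counts_from(day)
        bouts = find_sleep_bouts(immobile_minutes(c))
        lp = sleep_metrics(bouts, c, schedule, PeriodLabel.LP)
        dp = sleep_metrics(bouts, c, schedule, PeriodLabel.DP)
        assert lp.total_sleep_min == 10 and dp.total_sleep_min == 10
        assert lp.episode_count == 1 and dp.episode_count == 0


class TestSleepLatency:
    def test_bout_at_first_dark_minute(self, schedule):
        bouts = [SleepBout("f", 720, 30)]
        assert sleep_latency(bouts, schedule, PeriodLabel.DP) == 0

    def test_no_sleep_caps_at_period_length(self, schedule):
        assert sleep_latency([], schedule, PeriodLabel.DP) == 720

    def test_onset_zt_12_47(self, schedule):
        bouts = [SleepBout("f", 767, 10)]  # ZT 12:47
        assert sleep_latency(bouts, schedule, PeriodLabel.DP) == 47

    def test_full24_rejected(self, schedule):
        with pytest.raises(ValueError):
            sleep_latency([], schedule, PeriodLabel.FULL24)

    def test_lp_anchored_at_lights_on(self, schedule):
        bouts = [SleepBout("f", 100, 10)]
        assert sleep_latency(bouts, schedule, PeriodLabel.LP) == 100


class TestAveraging:
    def _tidy(self, per_fly_days):
        rows = []
        for fly, days in per_fly_days.items():
            for d, v in enumerate(days):
                rows.append(
                    {"fly_id": fly, "day": d, "period": "24",
                     "metric": "total_sleep_min", "value": v}
                )
        return pd.DataFrame(rows)

    def test_identical_days_equal_single_day(self):
        out = average_across_days(self._tidy({"a": [500, 500, 500]}))
        assert out["mean"].iloc[0] == 500

    def test_two_day_mean(self):
        out = average_across_days(self._tidy({"a": [400, 500]}))
        assert out["mean"].iloc[0] == 450

    def test_two_stage_oracle(self):
        rng = np.random.default_rng(4)
        panel = {f"f{i}": rng.uniform(0, 1440, 3).tolist() for i in range(6)}
        out = average_across_days(self._tidy(panel))
        fly_means = np.array([np.mean(v) for v in panel.values()])
        assert out["mean"].iloc[0] == pytest.approx(fly_means.mean())
        expected_sem = fly_means.std(ddof=1) / math.sqrt(len(fly_means))
        assert out["sem"].iloc[0] == pytest.approx(expected_sem)
        assert out["n"].iloc[0] == 6


class TestTimecourse:
    def test_all_sleep_day(self, schedule):
        zt, prof = sleep_timecourse(counts_from(np.zeros(1440)), schedule)
        assert len(prof) == 48 and (prof == 30).all()

    def test_no_sleep(self, schedule):
        day = day_from_bouts([])
        zt, prof = sleep_timecourse(counts_from(day), schedule)
        assert (prof == 0).all()

    def test_crafted_day_per_bin_membership(self, schedule):
        day = day_from_bouts([(10, 25), (60, 5)])
        zt, prof = sleep_timecourse(counts_from(day), schedule)
        # bout 1 spans minutes 10..34: 20 min in bin 0, 5 in bin 1; bout 2 in bin 2
        assert prof[0] == 20 and prof[1] == 5 and prof[2] == 5
        assert prof[3:].sum() == 0

    def test_values_bounded_by_bin_length(self, schedule):
        rng = np.random.default_rng(5)
        day = (rng.random(4320) < 0.5).astype(int)
        _, prof = sleep_timecourse(counts_from(day), schedule)
        assert ((prof >= 0) & (prof <= 30)).all()


class TestPerDayMetrics:
    def test_three_identical_days_average_to_one(self, schedule):
        day = day_from_bouts([(100, 60), (900, 200)])
        c = counts_from(np.tile(day, 3))
        tidy = per_day_metrics(c, schedule)
        assert sorted(tidy["day"].unique()) == [0, 1, 2]
        total = tidy[(tidy.metric == "total_sleep_min") & (tidy.period == "24")]
        assert (total["value"] == 260).all()
        out = average_across_days(tidy)
        row = out[(out.period == "24") & (out.metric == "total_sleep_min")]
        assert row["mean"].iloc[0] == 260

    def test_partial_days_dropped(self, schedule):
        c = counts_from(np.zeros(1440 + 700))
        tidy = per_day_metrics(c, schedule)
        assert tidy["day"].nunique() == 1
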