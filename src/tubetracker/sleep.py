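"""Sleep scoring by the 5-minute immobility rule and sleep architecture.

Fly sleep is defined operationally: any maximal run of at least five
consecutive 1-minute bins with zero activity counts is a sleep bout.  From
the bouts this module derives the standard architecture panel — total sleep,
episode count, mean and maximum episode duration, latency to sleep onset
after a lights transition, mean wake-run duration, and activity while active
(counts per waking minute) — split by full day (FULL24), light period (LP)
and dark period (DP), per day, then averaged across days per fly before any
group statistic is taken.

Attribution of a bout that spans the LP/DP boundary: its *minutes* are
credited to the period in which they occur (so LP + DP totals always add up
to the day), while the *bout itself* — for episode counts, means, maxima and
latency — belongs to the period containing its onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LightSchedule, PeriodLabel, period_of_minute
from .movement import BinnedCounts

__all__ = [
    "SleepBout",
    "SleepMetrics",
    "MIN_SLEEP_BOUT_MIN",
    "immobile_minutes",
    "find_sleep_bouts",
    "sleep_metrics",
    "sleep_latency",
    "per_day_metrics",
    "average_across_days",
    "sleep_timecourse",
]

#: Field-standard immobility run length (minutes) that qualifies as sleep.
MIN_SLEEP_BOUT_MIN = 5


@dataclass(frozen=True)
class SleepBout:
    """A maximal immobile run of at least MIN_SLEEP_BOUT_MIN minutes."""

    fly_id: str
    onset_min: int  # experiment minutes
    duration_min: int
    period: PeriodLabel | None = None  # LP/DP label of the onset minute

    def __post_init__(self) -> None:
        if self.duration_min < 1:
            raise ValueError("bout duration must be positive")

    @property
    def end_min(self) -> int:
        return self.onset_min + self.duration_min


@dataclass
class SleepMetrics:
    """Sleep-architecture panel for one fly over one analysis window."""

    fly_id: str
    period: PeriodLabel
    total_sleep_min: float
    episode_count: int
    mean_episode_min: float  # nan when no episodes
    max_episode_min: float  # nan when no episodes
    latency_min: float  # nan for FULL24
    mean_wake_min: float  # nan when no wake runs start in the period
    activity_while_active: float  # counts per waking minute; nan if none


def immobile_minutes(counts: BinnedCounts) -> np.ndarray:
    """Binary immobility per minute: 1 where the 1-min count is zero."""
    if counts.bin_length_s != 60:
        raise ValueError("immobility requires 1-min bins")
    return (counts.counts == 0).astype(np.uint8)


def find_sleep_bouts(
    immobility: np.ndarray,
    min_bout: int = MIN_SLEEP_BOUT_MIN,
    fly_id: str = "",
    start_minute: int = 0,
    schedule: LightSchedule | None = None,
) -> list[SleepBout]:
    """Maximal immobile runs of at least ``min_bout`` minutes.

    ``start_minute`` anchors the vector in experiment minutes so bout onsets
    are absolute; shorter immobile runs are wake by definition.
    """
    imm = np.asarray(immobility)
    if not set(np.unique(imm)) <= {0, 1}:
        raise ValueError("immobility vector must be binary")
    bouts: list[SleepBout] = []
    n = len(imm)
    i = 0
    while i < n:
        if imm[i]:
            j = i
            while j < n and imm[j]:
                j += 1
            if j - i >= min_bout:
                onset = start_minute + i
                period = None
                if schedule is not None:
                    zt = (onset - schedule.lights_on_zt0 // 60) % schedule.cycle_min
                    period = period_of_minute(zt, schedule)
                bouts.append(SleepBout(fly_id, onset, j - i, period))
            i = j
        else:
            i += 1
    return bouts


def _bout_mask(bouts: list[SleepBout], start_minute: int, n_minutes: int) -> np.ndarray:
    mask = np.zeros(n_minutes, dtype=bool)
    for b in bouts:
        lo = max(b.onset_min - start_minute, 0)
        hi = min(b.end_min - start_minute, n_minutes)
        if hi > lo:
            mask[lo:hi] = True
    return mask


def _period_mask(
    start_minute: int, n_minutes: int, schedule: LightSchedule, period: PeriodLabel
) -> np.ndarray:
    if period is PeriodLabel.FULL24:
        return np.ones(n_minutes, dtype=bool)
    zt = (
        np.arange(start_minute, start_minute + n_minutes)
        - schedule.lights_on_zt0 // 60
    ) % schedule.cycle_min
    lp = zt < schedule.photoperiod_min
    return lp if period is PeriodLabel.LP else ~lp


def sleep_latency(
    bouts: list[SleepBout],
    schedule: LightSchedule,
    period: PeriodLabel,
    day_start_min: int = 0,
) -> float:
    """Minutes from a lights transition to the first bout onset in the period.

    ``day_start_min`` is the experiment minute of the analysis day's ZT0.
    LP latency is anchored at lights-on, DP latency at lights-off; when no
    bout starts within the period the latency is capped at the period length.
    FULL24 has no anchoring transition and is rejected.
    """
    if period is PeriodLabel.FULL24:
        raise ValueError("latency is transition-anchored; use LP or DP")
    if period is PeriodLabel.LP:
        t0 = day_start_min
        length = schedule.photoperiod_min
    else:
        t0 = day_start_min + schedule.photoperiod_min
        length = schedule.cycle_min - schedule.photoperiod_min
    onsets = [b.onset_min - t0 for b in bouts if 0 <= b.onset_min - t0 < length]
    return float(min(onsets)) if onsets else float(length)


def sleep_metrics(
    bouts: list[SleepBout],
    counts: BinnedCounts,
    schedule: LightSchedule,
    period: PeriodLabel,
) -> SleepMetrics:
    """Architecture panel over the window spanned by ``counts``.

    ``counts`` must be 1-min bins; ``bouts`` must derive from the same
    counts.  Totals use in-bout minutes falling inside the period; episode
    statistics use bouts whose onset lies in the period and inside the
    window.  Waking minutes are all window minutes not covered by a bout.
    """
    if counts.bin_length_s != 60:
        raise ValueError("sleep metrics require 1-min bins")
    start = counts.start_minute
    n = len(counts)
    in_bout = _bout_mask(bouts, start, n)
    in_period = _period_mask(start, n, schedule, period)
    total_sleep = float((in_bout & in_period).sum())

    onset_bouts = [
        b
        for b in bouts
        if start <= b.onset_min < start + n
        and in_period[b.onset_min - start]
    ]
    durations = [b.duration_min for b in onset_bouts]

    wake = ~in_bout
    waking_min = int((wake & in_period).sum())
    if waking_min:
        awa = float(counts.counts[wake & in_period].sum()) / waking_min
    else:
        awa = math.nan

    # maximal wake runs whose onset minute lies in the period
    wake_durs: list[int] = []
    i = 0
    while i < n:
        if wake[i]:
            j = i
            while j < n and wake[j]:
                j += 1
            if in_period[i]:
                wake_durs.append(j - i)
            i = j
        else:
            i += 1

    if period is PeriodLabel.FULL24:
        latency = math.nan
    else:
        latency = sleep_latency(bouts, schedule, period, day_start_min=start)

    return SleepMetrics(
        fly_id=counts.fly_id,
        period=period,
        total_sleep_min=total_sleep,
        episode_count=len(durations),
        mean_episode_min=float(np.mean(durations)) if durations else math.nan,
        max_episode_min=float(max(durations)) if durations else math.nan,
        latency_min=latency,
        mean_wake_min=float(np.mean(wake_durs)) if wake_durs else math.nan,
        activity_while_active=awa,
    )


def _slice_counts(counts: BinnedCounts, lo_bin: int, hi_bin: int) -> BinnedCounts:
    return BinnedCounts(
        fly_id=counts.fly_id,
        bin_length_s=counts.bin_length_s,
        t_start=counts.t_start + lo_bin * counts.bin_length_s,
        counts=counts.counts[lo_bin:hi_bin],
        valid_bins=counts.valid_bins[lo_bin:hi_bin],
        periods=counts.periods[lo_bin:hi_bin] if counts.periods else [],
    )


def per_day_metrics(
    counts: BinnedCounts,
    schedule: LightSchedule,
    min_bout: int = MIN_SLEEP_BOUT_MIN,
) -> pd.DataFrame:
    """Tidy sleep metrics: one row per day x period x metric for one fly.

    Analysis days are complete cycles anchored at ZT0; a leading partial day
    and a trailing partial day are dropped.  Bouts are found once over the
    whole span, so a bout crossing midnight is not artificially split — its
    minutes are credited where they fall and the bout counts for its onset
    day and period.
    """
    if counts.bin_length_s != 60:
        raise ValueError("per-day metrics require 1-min bins")
    imm = immobile_minutes(counts)
    start = counts.start_minute
    bouts = find_sleep_bouts(
        imm, min_bout, fly_id=counts.fly_id, start_minute=start, schedule=schedule
    )
    cyc = schedule.cycle_min
    zt_of_start = (start - schedule.lights_on_zt0 // 60) % cyc
    first = (cyc - zt_of_start) % cyc  # bins until the first ZT0 boundary
    n_days = (len(counts) - first) // cyc
    rows = []
    for d in range(n_days):
        lo = first + d * cyc
        day_counts = _slice_counts(counts, lo, lo + cyc)
        for period in PeriodLabel:
            m = sleep_metrics(bouts, day_counts, schedule, period)
            for metric, value in (
                ("total_sleep_min", m.total_sleep_min),
                ("episode_count", m.episode_count),
                ("mean_episode_min", m.mean_episode_min),
                ("max_episode_min", m.max_episode_min),
                ("latency_min", m.latency_min),
                ("mean_wake_min", m.mean_wake_min),
                ("activity_while_active", m.activity_while_active),
            ):
                rows.append(
                    {
                        "fly_id": counts.fly_id,
                        "day": d,
                        "period": period.value,
                        "metric": metric,
                        "value": float(value),
                    }
                )
    return pd.DataFrame(rows)


def average_across_days(tidy: pd.DataFrame) -> pd.DataFrame:
    """Two-stage averaging: per-fly mean over days, then group mean +/- SEM.

    Input is the tidy frame of :func:`per_day_metrics` (possibly concatenated
    over flies).  Latency rows are nan for FULL24 and are dropped from group
    statistics rather than propagated.
    """
    if tidy.empty:
        raise ValueError("no complete days to average")
    per_fly = (
        tidy.groupby(["fly_id", "period", "metric"], as_index=False)["value"]
        .mean()
    )
    def _sem(x: pd.Series) -> float:
        x = x.dropna()
        if len(x) < 2:
            return math.nan
        return float(x.std(ddof=1) / math.sqrt(len(x)))

    grp = per_fly.groupby(["period", "metric"])["value"]
    out = grp.agg(mean="mean", sem=_sem, n="count").reset_index()
    return out


def sleep_timecourse(
    counts: BinnedCounts,
    schedule: LightSchedule,
    bin_min: int = 30,
    min_bout: int = MIN_SLEEP_BOUT_MIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Minutes of sleep per ZT-aligned ``bin_min`` bin (sleep profile).

    Returns ``(zt_bin_start_minutes, sleep_minutes)``; when the span covers
    several days, bins from the same ZT slot are averaged.  Incomplete bins
    are dropped.  Values lie in [0, bin_min].
    """
    if counts.bin_length_s != 60:
        raise ValueError("timecourse requires 1-min bins")
    imm = immobile_minutes(counts)
    start = counts.start_minute
    bouts = find_sleep_bouts(
        imm, min_bout, fly_id=counts.fly_id, start_minute=start, schedule=schedule
    )
    in_bout = _bout_mask(bouts, start, len(counts))
    zt_of_start = (start - schedule.lights_on_zt0 // 60) % schedule.cycle_min
    first = (-zt_of_start) % bin_min
    n_bins = (len(counts) - first) // bin_min
    slots = schedule.cycle_min // bin_min
    acc = np.zeros(slots)
    seen = np.zeros(slots)
    for b in range(n_bins):
        lo = first + b * bin_min
        zt = (zt_of_start + lo) % schedule.cycle_min
        slot = zt // bin_min
        acc[slot] += in_bout[lo : lo + bin_min].sum()
        seen[slot] += 1
    present = seen > 0
    zt_starts = np.arange(slots)[present] * bin_min
    return zt_starts, acc[present] / np.maximum(seen[present], 1)
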