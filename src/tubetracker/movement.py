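"""Per-second movement scoring and DAM-style binning.

Coordinate trajectories are reduced to a binary movement code (1 = moved this
second, 0 = did not), exactly the reduction applied to beam-cross counts by a
Drosophila Activity Monitor (DAM).  Two displacement cutoffs control the
scoring, both expressed as fractions of the fly body length (FBL) so settings
transfer across camera setups:

* a **minimum** threshold (20/50/100% FBL sensitivity settings) below which a
  displacement is treated as capture noise or posture change, not locomotion;
* a **maximum** cutoff (150% FBL) above which a displacement is physically
  unattainable in one second and is flagged as a tracking artifact; artifact
  seconds score 0 and are logged, never clamped.

A *virtual beam* — a software line at the physical infrared beam's coordinate
— converts the same trajectories into beam-cross events so tracker output can
be compared with a real DAM channel record one-for-one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import LightSchedule, PeriodLabel, Trajectory, period_of_minute

__all__ = [
    "ActivitySeries",
    "BinnedCounts",
    "fbl_threshold",
    "displacement",
    "classify_movement",
    "bin_counts",
    "virtual_beam",
]

#: Fraction of FBL used for the maximum plausible 1 s displacement.
MAX_CUTOFF_FRACTION = 1.5

#: Invalid-detection runs longer than this invalidate their minute bins.
MAX_INVALID_RUN_S = 60


@dataclass
class ActivitySeries:
    """Per-second binary movement for one fly, aligned to experiment time.

    ``moving[i]`` scores the second ``t0 + i``; ``artifact[i]`` marks seconds
    whose displacement exceeded the maximum cutoff (scored 0), and
    ``valid[i]`` mirrors the detection flags of the source records.
    """

    fly_id: str
    t0: int
    moving: np.ndarray
    artifact: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, dtype=np.uint8)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not set(np.unique(self.moving)) <= {0, 1}:
            raise ValueError("movement series must be binary")
        if self.moving[self.artifact].any():
            raise ValueError("artifact seconds must be scored 0")

    def __len__(self) -> int:
        return len(self.moving)


@dataclass
class BinnedCounts:
    """DAM-like integer counts per fixed-length bin, ZT0-aligned.

    ``valid_bins`` flags bins untouched by long invalid-detection runs; QC
    only — counts are reported for every complete bin.
    """

    fly_id: str
    bin_length_s: int
    t_start: int
    counts: np.ndarray
    valid_bins: np.ndarray
    periods: list[PeriodLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.valid_bins = np.asarray(self.valid_bins, dtype=bool)
        if (self.counts < 0).any() or (self.counts > self.bin_length_s).any():
            raise ValueError("bin counts must lie in [0, bin_length_s]")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def start_minute(self) -> int:
        """Experiment minute of the first bin."""
        return self.t_start // 60


def fbl_threshold(fbl_px: float, fraction: float) -> int:
    """Displacement cutoff in whole pixels for an FBL fraction.

    Round-half-up of ``fbl_px * fraction``, floored at 1 px: a 10 px fly at
    the 20/50/100% sensitivity settings yields 2/5/10 px, and the 150%
    maximum cutoff yields 15 px.
    """
    if fbl_px <= 0 or fraction <= 0:
        raise ValueError("fbl_px and fraction must be positive")
    return max(1, math.floor(fbl_px * fraction + 0.5))


def displacement(r1, r2) -> float:
    """Euclidean pixel distance between two valid track records."""
    if not (r1.valid and r2.valid):
        raise ValueError("displacement is undefined across invalid records")
    return math.hypot(r2.x - r1.x, r2.y - r1.y)


def classify_movement(
    traj: Trajectory, min_px: float, max_px: float | None = None
) -> ActivitySeries:
    """Binary movement code for a 1 Hz trajectory.

    Second ``t`` scores 1 iff ``min_px <= d <= max_px`` where ``d`` is the
    Euclidean displacement from the previous record; the minimum is inclusive
    (the fly must move *at least* the threshold distance).  Displacements
    above ``max_px`` score 0 and raise the artifact flag.  The first second
    and any second adjacent to an invalid detection score 0.
    """
    if not len(traj):
        raise ValueError("empty trajectory")
    if max_px is None:
        if traj.calibration is None:
            raise ValueError("need max_px or a calibrated trajectory")
        max_px = fbl_threshold(traj.calibration.fbl_px, MAX_CUTOFF_FRACTION)
    if min_px > max_px:
        raise ValueError("min_px must not exceed max_px")
    pos = traj.positions()
    valid = traj.valid_mask()
    n = len(traj)
    moving = np.zeros(n, dtype=np.uint8)
    artifact = np.zeros(n, dtype=bool)
    steps = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))
    pair_ok = valid[1:] & valid[:-1]
    moving[1:] = (pair_ok & (steps >= min_px) & (steps <= max_px)).astype(np.uint8)
    artifact[1:] = pair_ok & (steps > max_px)
    return ActivitySeries(traj.fly_id, traj.t0, moving, artifact, valid)


def _invalid_bin_mask(
    valid: np.ndarray, start: int, n_bins: int, bin_length_s: int
) -> np.ndarray:
    """True for bins overlapping an invalid run longer than MAX_INVALID_RUN_S."""
    bad = np.zeros(n_bins, dtype=bool)
    i = 0
    n = len(valid)
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            if j - i > MAX_INVALID_RUN_S:
                lo = (i - start) // bin_length_s
                hi = (j - 1 - start) // bin_length_s + 1
                bad[max(lo, 0) : max(min(hi, n_bins), 0)] = True
            i = j
        else:
            i += 1
    return bad


def bin_counts(
    series: ActivitySeries,
    bin_length_s: int,
    schedule: LightSchedule | None = None,
) -> BinnedCounts:
    """Sum a binary movement series into fixed-length bins.

    Bins are aligned to ZT0 when a schedule is given (leading seconds before
    the first aligned boundary are dropped), otherwise to the series start.
    Partial trailing bins are dropped — analyses operate on whole bins only.
    """
    if bin_length_s <= 0:
        raise ValueError("bin length must be positive")
    anchor = schedule.lights_on_zt0 if schedule is not None else series.t0
    # first bin boundary at or after the series start
    off = series.t0 - anchor
    if off < 0:
        raise ValueError("series starts before the schedule anchor")
    start = (-off) % bin_length_s  # index into the series of the first bin
    n_bins = (len(series) - start) // bin_length_s
    if n_bins < 0:
        n_bins = 0
    span = series.moving[start : start + n_bins * bin_length_s]
    counts = span.reshape(n_bins, bin_length_s).sum(axis=1)
    t_start = series.t0 + start
    bad = _invalid_bin_mask(series.valid, start, n_bins, bin_length_s)
    periods = []
    if schedule is not None:
        for b in range(n_bins):
            zt = ((t_start + b * bin_length_s - schedule.lights_on_zt0) // 60) % (
                schedule.cycle_min
            )
            periods.append(period_of_minute(zt, schedule))
    return BinnedCounts(
        fly_id=series.fly_id,
        bin_length_s=bin_length_s,
        t_start=t_start,
        counts=counts,
        valid_bins=~bad,
        periods=periods,
    )


def virtual_beam(traj: Trajectory, beam_x: float | None = None) -> np.ndarray:
    """Per-second virtual beam-cross events (1 = crossed, 0 = not crossed).

    Second ``t`` scores 1 iff the tube-axis positions at ``t-1`` and ``t``
    lie strictly on opposite sides of the beam, or the fly lands exactly on
    the beam coming from off-beam.  Consecutive on-beam samples count once
    (a fly resting on the beam is not re-counted), and pairs involving an
    invalid detection never score.
    """
    if not len(traj):
        raise ValueError("empty trajectory")
    if beam_x is None:
        if traj.calibration is None:
            raise ValueError("need beam_x or a calibrated trajectory")
        beam_x = traj.calibration.default_beam()
    axis = traj.axis_positions() if traj.calibration is not None else traj.positions()[:, 0]
    valid = traj.valid_mask()
    prev = axis[:-1] - beam_x
    cur = axis[1:] - beam_x
    crossed = (prev * cur < 0) | ((cur == 0) & (prev != 0))
    events = np.zeros(len(traj), dtype=np.uint8)
    events[1:] = (crossed & valid[1:] & valid[:-1]).astype(np.uint8)
    return events
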