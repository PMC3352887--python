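"""Locomotor analytics and place preference.

Distance, speed and population activity are computed straight from the 1 Hz
coordinates — information a beam-cross monitor cannot provide.  Distances use
the full 2-D Euclidean displacement (the tube is only 5 mm wide, so the
difference from an axis projection is small but real) converted to mm by the
linear ROI-axis-to-tube-length map.  Place preference divides the tube axis
into 10 equal sections with section 10 adjacent to the food plug, and tallies
dwell seconds per section per time bin, optionally restricted to seconds the
fly was asleep or awake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Calibration, LightSchedule, Trajectory
from .movement import MAX_CUTOFF_FRACTION, ActivitySeries, fbl_threshold
from .sleep import SleepBout, _bout_mask

__all__ = [
    "DistanceSeries",
    "OccupancyMatrix",
    "px_to_mm",
    "distance_series",
    "subsample_distance",
    "speed_series",
    "percent_active",
    "section_of",
    "occupancy",
    "occupancy_proportions",
]

N_SECTIONS = 10


@dataclass
class DistanceSeries:
    """Per-bin distance in mm for one fly."""

    fly_id: str
    bin_length_s: int
    t_start: int
    mm: np.ndarray

    def __post_init__(self) -> None:
        self.mm = np.asarray(self.mm, dtype=float)
        if (self.mm < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def total_mm(self) -> float:
        return float(self.mm.sum())


@dataclass
class OccupancyMatrix:
    """Dwell seconds per tube section (rows 1..10) per time bin (columns)."""

    fly_id: str
    bin_length_s: int
    t_start: int
    dwell: np.ndarray  # (N_SECTIONS, n_bins)
    state: str = "none"  # none | asleep | awake

    def __post_init__(self) -> None:
        self.dwell = np.asarray(self.dwell, dtype=float)
        if self.dwell.shape[0] != N_SECTIONS:
            raise ValueError(f"occupancy must have {N_SECTIONS} section rows")


def px_to_mm(axis_px: float, calibration: Calibration) -> float:
    """Convert a distance along the tube axis from pixels to mm."""
    if calibration.axis_length_px <= 0:
        raise ValueError("degenerate ROI")
    return axis_px * calibration.mm_per_px


def _step_lengths_mm(
    traj: Trajectory, max_px: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-second step lengths in mm and a validity mask for each step.

    Steps adjacent to invalid detections, and artifact steps above the
    maximum displacement cutoff, contribute zero distance.
    """
    cal = traj.calibration
    if cal is None:
        raise ValueError("distance requires a calibrated trajectory")
    if max_px is None:
        max_px = fbl_threshold(cal.fbl_px, MAX_CUTOFF_FRACTION)
    pos = traj.positions()
    valid = traj.valid_mask()
    steps_px = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))
    ok = valid[1:] & valid[:-1] & (steps_px <= max_px)
    return steps_px * cal.mm_per_px, ok


def distance_series(
    traj: Trajectory, bin_length_s: int = 60, max_px: float | None = None
) -> DistanceSeries:
    """Distance travelled per bin, in mm, from consecutive 1 Hz displacements.

    The step from sample ``t`` to ``t+1`` is credited to second ``t`` — the
    second during which the movement happened — so a fly moving 2 px/s for a
    full minute logs exactly 60 steps in that minute's bin.  A trailing bin
    not covered by a full complement of steps is dropped.
    """
    if not len(traj):
        raise ValueError("empty trajectory")
    mm, ok = _step_lengths_mm(traj, max_px)
    mm = np.where(ok, mm, 0.0)  # step i spans seconds [i, i+1)
    n_bins = len(mm) // bin_length_s
    binned = mm[: n_bins * bin_length_s].reshape(n_bins, bin_length_s).sum(axis=1)
    return DistanceSeries(traj.fly_id, bin_length_s, traj.t0, binned)


def subsample_distance(
    traj: Trajectory, stride_s: int, max_px: float | None = None
) -> float:
    """Total distance in mm when the trajectory is decimated to one sample
    every ``stride_s`` seconds.

    By the triangle inequality this never exceeds the 1 Hz polyline total;
    paths with direction reversals between retained samples lose distance,
    which is why coarser capture rates systematically under-report
    locomotion.  No artifact cutoff is applied by default (``max_px=None``):
    the quantity measured is pure decimation loss on the recorded polyline,
    so at stride 1 it equals the unfiltered 1 Hz total exactly.
    """
    if stride_s < 1 or int(stride_s) != stride_s:
        raise ValueError("stride must be a positive integer")
    cal = traj.calibration
    if cal is None:
        raise ValueError("distance requires a calibrated trajectory")
    if max_px is None:
        max_px = np.inf
    recs = traj.records[:: int(stride_s)]
    pos = np.asarray([(r.x, r.y) for r in recs])
    valid = np.asarray([r.valid for r in recs])
    steps = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))
    ok = valid[1:] & valid[:-1] & (steps <= max_px)
    return float(np.where(ok, steps, 0.0).sum() * cal.mm_per_px)


def speed_series(distances: DistanceSeries) -> np.ndarray:
    """Mean speed per bin, mm/s."""
    return distances.mm / distances.bin_length_s


def percent_active(
    series: list[ActivitySeries], bin_length_s: int = 1800
) -> np.ndarray:
    """Percent of flies with at least one movement per bin (Fig-style % Activity).

    All series must be aligned (same start and length); partial trailing bins
    are dropped.
    """
    if not series:
        raise ValueError("need at least one fly")
    n = len(series[0])
    if any(len(s) != n or s.t0 != series[0].t0 for s in series):
        raise ValueError("activity series must be aligned")
    n_bins = n // bin_length_s
    active = np.zeros((len(series), n_bins))
    for i, s in enumerate(series):
        trimmed = s.moving[: n_bins * bin_length_s].reshape(n_bins, bin_length_s)
        active[i] = trimmed.any(axis=1)
    return active.mean(axis=0) * 100.0


def section_of(
    axis_px: float, calibration: Calibration, n_sections: int = N_SECTIONS
) -> int:
    """Tube section index 1..n for an axis position; section n abuts the food.

    Sections are equal-width half-open partitions of the ROI axis.  The
    food-end boundary point belongs to section n and the far-end boundary to
    section 1.
    """
    lo = calibration.axis_origin
    length = calibration.axis_length_px
    if not lo <= axis_px <= lo + length:
        raise ValueError(f"axis position {axis_px} outside ROI")
    frac = (axis_px - lo) / length
    idx = min(int(frac * n_sections), n_sections - 1)  # 0-based from axis origin
    if calibration.food_end == "high":
        return idx + 1
    return n_sections - idx


def occupancy(
    traj: Trajectory,
    schedule: LightSchedule | None = None,
    bin_length_s: int = 60,
    state_filter: str = "none",
    bouts: list[SleepBout] | None = None,
) -> OccupancyMatrix:
    """Dwell seconds per tube section per time bin.

    Each valid 1 Hz record contributes one second to the section containing
    its axis position.  With ``state_filter`` 'asleep' or 'awake', only
    seconds whose minute falls inside (respectively outside) a sleep bout are
    tallied; the asleep and awake matrices therefore partition the
    unconditioned one cell-wise.  Bins are ZT0-aligned when a schedule is
    given; partial trailing bins are dropped.
    """
    if state_filter not in ("none", "asleep", "awake"):
        raise ValueError("state_filter must be none|asleep|awake")
    if state_filter != "none" and bouts is None:
        raise ValueError("state-conditioned occupancy requires sleep bouts")
    cal = traj.calibration
    if cal is None:
        raise ValueError("occupancy requires a calibrated trajectory")
    n = len(traj)
    t0 = traj.t0
    anchor = schedule.lights_on_zt0 if schedule is not None else t0
    start = (-(t0 - anchor)) % bin_length_s
    n_bins = max((n - start) // bin_length_s, 0)
    dwell = np.zeros((N_SECTIONS, n_bins))
    axis = traj.axis_positions()
    valid = traj.valid_mask()

    lo = cal.axis_origin
    frac = (np.clip(axis, lo, lo + cal.axis_length_px) - lo) / cal.axis_length_px
    idx = np.minimum((frac * N_SECTIONS).astype(int), N_SECTIONS - 1)
    secs = idx + 1 if cal.food_end == "high" else N_SECTIONS - idx

    keep = valid.copy()
    if state_filter != "none":
        first_min = t0 // 60
        n_min = (t0 + n - 1) // 60 - first_min + 1
        mask_min = _bout_mask(bouts or [], first_min, n_min)
        asleep = mask_min[(t0 + np.arange(n)) // 60 - first_min]
        keep &= asleep if state_filter == "asleep" else ~asleep
    i = np.arange(start, start + n_bins * bin_length_s)
    i = i[keep[i]]
    np.add.at(dwell, (secs[i] - 1, (i - start) // bin_length_s), 1.0)
    return OccupancyMatrix(
        fly_id=traj.fly_id,
        bin_length_s=bin_length_s,
        t_start=t0 + start,
        dwell=dwell,
        state=state_filter,
    )


def occupancy_proportions(matrix: OccupancyMatrix) -> np.ndarray:
    """Fraction of total dwell time per section, collapsed over time bins."""
    totals = matrix.dwell.sum(axis=1)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("empty occupancy matrix")
    return totals / grand
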