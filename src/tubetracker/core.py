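"""Shared domain types and Zeitgeber-time arithmetic.

Flies live singly in 65x5x5 mm glass tubes imaged from above; every analysis
stage works on 1 Hz positional records expressed in pixels inside a
rectangular region of interest (ROI), one ROI per fly.  Light/dark phase is
expressed in Zeitgeber time (ZT): ZT 0 is lights-on, and with the standard
12:12 schedule ZT 720 min is the first dark minute.

Conventions adopted package-wide:

* coordinates are 0-based pixels, origin at the frame's top-left, y downward;
* the tube axis is the longer dimension of the ROI, and 1-D analyses (virtual
  beam, tube sections) project positions onto it;
* light intervals are half-open [lights-on, lights-off): the lights-off minute
  belongs to the dark period.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Rect",
    "TrackRecord",
    "Trajectory",
    "Calibration",
    "LightSchedule",
    "PeriodLabel",
    "zt_minute",
    "in_light",
]


class UnentrainedError(ValueError):
    """Raised when a timestamp precedes the first lights-on transition."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle: half-open [x0, x0+width) x [y0, y0+height)."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("Rect must have positive width and height")

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )


@dataclass(frozen=True)
class TrackRecord:
    """One fly's position at one timestamp (1 Hz nominal cadence).

    ``valid`` is False when detection failed at this tick; the coordinates
    then carry the last known position and must not be scored as movement.
    """

    fly_id: str
    t: int
    x: float
    y: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("timestamp must be nonnegative")


@dataclass(frozen=True)
class Calibration:
    """Per-tube geometry: fly body length, ROI, beam position, physical scale.

    ``food_end`` names the end of the tube axis holding the food plug:
    ``"high"`` means the food sits at the large-coordinate end of the axis.
    """

    fbl_px: float
    roi: Rect
    food_end: str = "high"
    beam_x: float | None = None
    tube_length_mm: float = 65.0

    def __post_init__(self) -> None:
        if self.fbl_px <= 0:
            raise ValueError("fbl_px must be positive")
        if self.tube_length_mm <= 0:
            raise ValueError("tube_length_mm must be positive")
        if self.food_end not in ("high", "low"):
            raise ValueError("food_end must be 'high' or 'low'")
        if self.beam_x is not None and not (
            self.axis_origin <= self.beam_x < self.axis_origin + self.axis_length_px
        ):
            raise ValueError("beam_x must lie inside the ROI tube axis")

    @property
    def axis(self) -> str:
        """Tube axis: the longer ROI dimension ('x' or 'y')."""
        return "x" if self.roi.width >= self.roi.height else "y"

    @property
    def axis_origin(self) -> int:
        return self.roi.x0 if self.axis == "x" else self.roi.y0

    @property
    def axis_length_px(self) -> int:
        return max(self.roi.width, self.roi.height)

    @property
    def mm_per_px(self) -> float:
        return self.tube_length_mm / self.axis_length_px

    def axis_position(self, x: float, y: float) -> float:
        """Project a 2-D pixel position onto the tube axis."""
        return x if self.axis == "x" else y

    def default_beam(self) -> float:
        """Beam position used when none was measured: the tube midpoint."""
        if self.beam_x is not None:
            return self.beam_x
        return self.axis_origin + self.axis_length_px / 2.0


@dataclass
class Trajectory:
    """Ordered 1 Hz track records for one fly, plus its calibration."""

    fly_id: str
    records: list[TrackRecord] = field(default_factory=list)
    calibration: Calibration | None = None

    def __post_init__(self) -> None:
        for r in self.records:
            if r.fly_id != self.fly_id:
                raise ValueError("all records must share the trajectory fly_id")
        times = [r.t for r in self.records]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("record timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def t0(self) -> int:
        if not self.records:
            raise ValueError("empty trajectory has no start time")
        return self.records[0].t

    def times(self) -> np.ndarray:
        return np.asarray([r.t for r in self.records], dtype=np.int64)

    def positions(self) -> np.ndarray:
        """(n, 2) array of x, y pixel coordinates."""
        return np.asarray([(r.x, r.y) for r in self.records], dtype=float)

    def valid_mask(self) -> np.ndarray:
        return np.asarray([r.valid for r in self.records], dtype=bool)

    def axis_positions(self) -> np.ndarray:
        if self.calibration is None:
            raise ValueError("trajectory has no calibration")
        pos = self.positions()
        return pos[:, 0] if self.calibration.axis == "x" else pos[:, 1]


@dataclass(frozen=True)
class LightSchedule:
    """LD cycle: lights-on anchor (experiment seconds) and cycle geometry."""

    lights_on_zt0: int = 0
    photoperiod_min: int = 720
    cycle_min: int = 1440

    def __post_init__(self) -> None:
        if not 0 < self.photoperiod_min < self.cycle_min:
            raise ValueError("require 0 < photoperiod_min < cycle_min")


class PeriodLabel(enum.Enum):
    """Analysis window: full day, light period, or dark period."""

    FULL24 = "24"
    LP = "LP"
    DP = "DP"


def zt_minute(t: int, schedule: LightSchedule) -> int:
    """Minutes since the most recent lights-on, modulo the cycle length.

    Parameters
    ----------
    t : experiment time in seconds; must not precede the first lights-on.
    """
    if t < schedule.lights_on_zt0:
        raise UnentrainedError(
            f"t={t} precedes first lights-on at {schedule.lights_on_zt0}"
        )
    return ((t - schedule.lights_on_zt0) // 60) % schedule.cycle_min


def in_light(t: int, schedule: LightSchedule) -> bool:
    """True iff ``t`` falls in the light phase ([lights-on, lights-off))."""
    return zt_minute(t, schedule) < schedule.photoperiod_min


def period_of_minute(zt_min: int, schedule: LightSchedule) -> PeriodLabel:
    """LP/DP label of a ZT minute."""
    if not 0 <= zt_min < schedule.cycle_min:
        raise ValueError("ZT minute outside the cycle")
    return PeriodLabel.LP if zt_min < schedule.photoperiod_min else PeriodLabel.DP
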