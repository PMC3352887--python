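"""Synthetic fly trajectories and rendered frames with known ground truth.

No recorded videos or coordinate files accompany the tube assay, so every
stage of the pipeline is exercised against a simulator instead.  A single fly
in a 65 mm tube alternates between *rest* and *active* bouts whose durations
are exponentially distributed with means modulated by a 24 h square wave
(light vs dark phase) — the minimal memoryless model that still produces a
circadian rest/activity profile and makes the expected rest fraction
analytic: within one phase, E[rest fraction] = rest_mean / (rest_mean +
active_mean).

While active the fly performs a reflected random walk along the tube axis
with a persistent heading, occasional reversals, and a configurable bias
toward the food end (flies patrol but favour the food).  While resting it
holds position up to Gaussian positional jitter far below the movement
threshold, so ground-truth rest scores as immobility downstream.

Frames are rendered as a dark filled ellipse (major axis = one fly body
length) on a light background with optional additive Gaussian noise; the
intensity constants are arbitrary fixture values chosen for high contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .core import Calibration, LightSchedule, Rect, TrackRecord, Trajectory

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_trajectory",
    "render_frames",
    "ground_truth_beam",
    "default_calibration",
    "default_schedule",
]

BACKGROUND_INTENSITY = 220
FLY_INTENSITY = 40


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated fly.

    Defaults describe a wild-type-like fly: 12:12 LD, 10 px body length in a
    260 px (65 mm) tube, more consolidated rest in the dark, ~1 mm/s walking
    steps, and a mild drift toward the food end.
    """

    seed: int = 0
    days: float = 1.0
    tube_axis_px: int = 260
    tube_width_px: int = 20
    margin_px: int = 5
    fbl_px: float = 10.0
    rest_mean_light_min: float = 10.0
    active_mean_light_min: float = 10.0
    rest_mean_dark_min: float = 24.0
    active_mean_dark_min: float = 6.0
    active_speed_mean_px: float = 4.0
    active_speed_sd_px: float = 2.0
    rest_jitter_sd_px: float = 0.3
    food_bias: float = 0.3
    reversal_prob: float = 0.05
    detection_noise_sd: float = 0.0
    photoperiod_min: int = 720
    cycle_min: int = 1440
    fly_id: str = "sim"

    def __post_init__(self) -> None:
        if self.days <= 0:
            raise ValueError("days must be positive")
        for name in ("tube_axis_px", "tube_width_px", "fbl_px",
                     "rest_mean_light_min", "rest_mean_dark_min",
                     "active_speed_mean_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.active_mean_light_min < 0 or self.active_mean_dark_min < 0:
            raise ValueError("active bout means must be nonnegative")
        if not 0 <= self.food_bias <= 1:
            raise ValueError("food_bias must lie in [0, 1]")
        if self.rest_jitter_sd_px < 0 or self.detection_noise_sd < 0:
            raise ValueError("noise scales must be nonnegative")

    @property
    def n_seconds(self) -> int:
        return int(round(self.days * self.cycle_min)) * 60

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (
            self.tube_width_px + 2 * self.margin_px,
            self.tube_axis_px + 2 * self.margin_px,
        )


@dataclass
class GroundTruth:
    """What actually happened: per-second state, true positions, rest bouts."""

    state: np.ndarray  # 1 = active, 0 = rest, per second
    x: np.ndarray  # true axis (x) position per second, pixels
    y: np.ndarray
    rest_bouts: list[tuple[int, int]] = field(default_factory=list)
    # (onset_minute, duration_minutes) of runs >= 5 min without any active second

    @property
    def rest_bout_minutes(self) -> int:
        return sum(d for _, d in self.rest_bouts)


def default_calibration(params: SimParams) -> Calibration:
    m = params.margin_px
    roi = Rect(m, m, params.tube_axis_px, params.tube_width_px)
    return Calibration(
        fbl_px=params.fbl_px,
        roi=roi,
        food_end="high",
        beam_x=m + params.tube_axis_px / 2.0,
        tube_length_mm=65.0,
    )


def default_schedule(params: SimParams) -> LightSchedule:
    return LightSchedule(0, params.photoperiod_min, params.cycle_min)


def _bout_means(params: SimParams, t: int) -> tuple[float, float]:
    """(rest_mean_s, active_mean_s) for the phase containing second ``t``."""
    light = (t // 60) % params.cycle_min < params.photoperiod_min
    if light:
        return params.rest_mean_light_min * 60, params.active_mean_light_min * 60
    return params.rest_mean_dark_min * 60, params.active_mean_dark_min * 60


def simulate_trajectory(params: SimParams) -> tuple[Trajectory, GroundTruth]:
    """Simulate one fly at 1 Hz; reproducible per seed.

    Rest bouts in the ground truth are expressed on the minute grid (a
    ground-truth rest minute contains no active second, matching what a
    perfect 1-min activity binning would see) as maximal runs of >= 5 min.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_seconds
    state = np.zeros(n, dtype=np.uint8)
    cal = default_calibration(params)
    lo = float(cal.axis_origin)
    hi = lo + cal.axis_length_px - 1e-6
    x = np.empty(n)
    y = np.empty(n)
    y_center = params.margin_px + params.tube_width_px / 2.0
    y_lo = float(cal.roi.y0)
    y_hi = float(cal.roi.y1) - 1e-6
    # artifact-safe step cap: stay strictly below the 150% FBL cutoff
    step_cap = 1.4 * params.fbl_px

    pos = lo + 0.8 * cal.axis_length_px  # start near (not on) the food
    heading = -1.0
    active = False  # wake up from rest first
    t = 0
    while t < n:
        rest_mean, active_mean = _bout_means(params, t)
        mean = active_mean if active else rest_mean
        if mean <= 0:
            active = not active
            continue
        dur = max(1, int(round(rng.exponential(mean))))
        end = min(t + dur, n)
        if active:
            for i in range(t, end):
                if rng.random() < params.reversal_prob:
                    toward_food = rng.random() < 0.5 + params.food_bias / 2.0
                    heading = 1.0 if toward_food else -1.0
                speed = float(
                    np.clip(
                        rng.normal(
                            params.active_speed_mean_px, params.active_speed_sd_px
                        ),
                        0.0,
                        step_cap,
                    )
                )
                pos += heading * speed
                if pos > hi:
                    pos = 2 * hi - pos
                    heading = -1.0
                elif pos < lo:
                    pos = 2 * lo - pos
                    heading = 1.0
                pos = float(np.clip(pos, lo, hi))
                x[i] = pos
                y[i] = float(
                    np.clip(rng.normal(y_center, 1.0), y_lo, y_hi)
                )
            state[t:end] = 1
        else:
            k = end - t
            x[t:end] = np.clip(
                pos + rng.normal(0.0, params.rest_jitter_sd_px, size=k), lo, hi
            )
            y[t:end] = np.clip(
                y_center + rng.normal(0.0, params.rest_jitter_sd_px, size=k),
                y_lo,
                y_hi,
            )
        active = not active
        t = end

    records = [
        TrackRecord(params.fly_id, i, float(x[i]), float(y[i]), True)
        for i in range(n)
    ]
    traj = Trajectory(params.fly_id, records, calibration=cal)

    n_min = n // 60
    active_min = state[: n_min * 60].reshape(n_min, 60).max(axis=1)
    rest_bouts: list[tuple[int, int]] = []
    i = 0
    while i < n_min:
        if not active_min[i]:
            j = i
            while j < n_min and not active_min[j]:
                j += 1
            if j - i >= 5:
                rest_bouts.append((i, j - i))
            i = j
        else:
            i += 1
    return traj, GroundTruth(state=state, x=x, y=y, rest_bouts=rest_bouts)


def render_frames(
    truth: GroundTruth,
    params: SimParams,
    noise_sd: float | None = None,
    start: int = 0,
    n_frames: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Render 8-bit grayscale frames for a slice of the ground truth.

    Returns ``(frames, reference)`` where the reference is the empty,
    noise-free background the tracker subtracts.  Each frame paints a dark
    filled ellipse (major axis = fbl_px along the tube) at the true position
    and adds Gaussian noise of sd ``noise_sd`` (defaults to the params'
    detection_noise_sd).
    """
    if noise_sd is None:
        noise_sd = params.detection_noise_sd
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    if n_frames is None:
        n_frames = len(truth.x) - start
    shape = params.frame_shape
    reference = np.full(shape, BACKGROUND_INTENSITY, dtype=np.uint8)
    frames: list[np.ndarray] = []
    for i in range(start, start + n_frames):
        cx, cy = truth.x[i], truth.y[i]
        if not (0 <= cx < shape[1] and 0 <= cy < shape[0]):
            raise ValueError(f"true position ({cx}, {cy}) outside the frame")
        frame = np.full(shape, float(BACKGROUND_INTENSITY))
        rr, cc = draw_ellipse(
            cy, cx, params.fbl_px * 0.2, params.fbl_px / 2.0, shape=shape
        )
        frame[rr, cc] = FLY_INTENSITY
        if noise_sd > 0:
            frame += rng.normal(0.0, noise_sd, size=shape)
        frames.append(np.clip(frame, 0, 255).astype(np.uint8))
    return frames, reference


def ground_truth_beam(truth: GroundTruth, beam_x: float) -> np.ndarray:
    """Per-second beam-cross log computed directly from the true positions.

    The crossing rule matches the virtual-beam definition: strict sign
    change across the beam, or an exact landing on it from off-beam.
    """
    xs = truth.x
    ev = np.zeros(len(xs), dtype=np.uint8)
    for t in range(1, len(xs)):
        prev = xs[t - 1] - beam_x
        cur = xs[t] - beam_x
        ev[t] = 1 if (prev * cur < 0 or (cur == 0 and prev != 0)) else 0
    return ev
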