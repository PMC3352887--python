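"""Centroid tracking by reference-image subtraction.

The imaging model is a dark fly on a light background.  A reference image of
the empty tubes is subtracted from each incoming frame; pixels whose absolute
difference exceeds a contrast threshold form a binary mask, connected
components inside each fly's ROI are size-filtered, and the largest survivor's
centroid is recorded at 1 Hz as a textual X/Y coordinate.

The reference is static for the whole run (no background-model updating) and
each track job is a discrete, non-overlapping ROI containing a single fly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from skimage import measure

from .core import Rect, TrackRecord

__all__ = [
    "TrackJob",
    "Detection",
    "build_reference",
    "difference_mask",
    "detect_fly",
    "track_stream",
    "estimate_fbl",
    "to_gray",
]

# ITU-R 601 luma weights for incidental colour input.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class TrackJob:
    """One ROI containing exactly one fly, tracked independently."""

    fly_id: str
    roi: Rect
    contrast_threshold: float = 60.0
    min_area: int = 6
    max_area: int = 400

    def __post_init__(self) -> None:
        if self.contrast_threshold <= 0:
            raise ValueError("contrast_threshold must be positive")
        if not 0 < self.min_area <= self.max_area:
            raise ValueError("require 0 < min_area <= max_area")


@dataclass(frozen=True)
class Detection:
    """A size-filtered connected component: sub-pixel centroid plus extent."""

    x: float
    y: float
    area: int
    bbox: Rect
    major_axis_px: float


def to_gray(frame: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) colour frame to grayscale; pass 2-D through."""
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 3:
        return frame.astype(float) @ _LUMA
    raise ValueError(f"unsupported frame shape {frame.shape}")


def build_reference(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Pixel-wise median of the supplied frames.

    The median is robust to a fly transiently occupying a pixel in a minority
    of the snapshots, so a usable empty-tube reference can be assembled even
    if the arena was not perfectly vacant.
    """
    frames = [np.asarray(to_gray(f), dtype=float) for f in frames]
    if not frames:
        raise ValueError("need at least one frame to build a reference")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all reference frames must share one shape")
    return np.median(np.stack(frames), axis=0)


def difference_mask(
    frame: np.ndarray, reference: np.ndarray, contrast_threshold: float
) -> np.ndarray:
    """Binary mask of pixels differing from the reference by more than the threshold."""
    frame = to_gray(np.asarray(frame))
    reference = np.asarray(reference)
    if frame.shape != reference.shape:
        raise ValueError(
            f"frame shape {frame.shape} != reference shape {reference.shape}"
        )
    if contrast_threshold <= 0:
        raise ValueError("contrast_threshold must be positive")
    return np.abs(frame.astype(float) - reference.astype(float)) > contrast_threshold


def _component_extent(rows: np.ndarray, cols: np.ndarray) -> float:
    """Largest pairwise extent of a pixel set, in pixels.

    Pixel centres that are d apart span d+1 pixels end to end, so a straight
    10-pixel fly measures 10.
    """
    pts = np.column_stack([rows, cols]).astype(float)
    if len(pts) == 1:
        return 1.0
    # components are size-capped by the job's max_area, so O(n^2) is cheap
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max())) + 1.0


def detect_fly(mask: np.ndarray, job: TrackJob) -> Detection | None:
    """Extract the fly from a difference mask within one track job's ROI.

    8-connected components are filtered to ``[min_area, max_area]`` pixels;
    the largest survivor is returned (area ties broken by the smaller
    top-left bbox corner, for deterministic output).  ``None`` means no
    credible fly-sized component this tick — a valid outcome.
    """
    roi = job.roi
    sub = np.asarray(mask)[roi.y0 : roi.y1, roi.x0 : roi.x1]
    labels = measure.label(sub, connectivity=2)
    best: tuple[int, int, int] | None = None  # (-area, y0, x0) sort key
    best_coords: np.ndarray | None = None
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        area = len(rows)
        if not job.min_area <= area <= job.max_area:
            continue
        key = (-area, int(rows.min()), int(cols.min()))
        if best is None or key < best:
            best = key
            best_coords = (rows, cols)
    if best_coords is None:
        return None
    rows, cols = best_coords
    cx = float(cols.mean()) + roi.x0
    cy = float(rows.mean()) + roi.y0
    bbox = Rect(
        int(cols.min()) + roi.x0,
        int(rows.min()) + roi.y0,
        int(cols.max() - cols.min()) + 1,
        int(rows.max() - rows.min()) + 1,
    )
    return Detection(
        x=cx,
        y=cy,
        area=len(rows),
        bbox=bbox,
        major_axis_px=_component_extent(rows, cols),
    )


def _roi_center(roi: Rect) -> tuple[float, float]:
    return (roi.x0 + roi.width / 2.0, roi.y0 + roi.height / 2.0)


def track_stream(
    frame_source: Iterable[np.ndarray],
    jobs: Sequence[TrackJob],
    reference: np.ndarray,
    interval_s: int = 1,
    t0: int = 0,
) -> dict[str, list[TrackRecord]]:
    """Run all track jobs over a frame stream, one record per job per tick.

    Frames are assumed to arrive at 1 Hz; ``interval_s`` decimates the stream
    so one tick is recorded every ``interval_s`` frames.  When detection fails
    for a job, a record carrying the last known position with ``valid=False``
    is emitted (the ROI centre before any detection has succeeded), so the
    output always has one row per tick and downstream code can skip invalid
    displacement pairs explicitly.

    The frame source simply running out ends the run cleanly.
    """
    if interval_s < 1:
        raise ValueError("interval_s must be >= 1")
    ids = [j.fly_id for j in jobs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate fly_id across track jobs")
    for i, a in enumerate(jobs):
        for b in jobs[i + 1 :]:
            if a.roi.overlaps(b.roi):
                raise ValueError(
                    f"track jobs {a.fly_id!r} and {b.fly_id!r} have overlapping ROIs"
                )
    out: dict[str, list[TrackRecord]] = {j.fly_id: [] for j in jobs}
    last: dict[str, tuple[float, float]] = {
        j.fly_id: _roi_center(j.roi) for j in jobs
    }
    tick = 0
    for i, frame in enumerate(frame_source):
        if i % interval_s:
            continue
        t = t0 + tick * interval_s
        tick += 1
        for job in jobs:
            mask = difference_mask(frame, reference, job.contrast_threshold)
            det = detect_fly(mask, job)
            if det is None:
                x, y = last[job.fly_id]
                out[job.fly_id].append(
                    TrackRecord(job.fly_id, t, x, y, valid=False)
                )
            else:
                last[job.fly_id] = (det.x, det.y)
                out[job.fly_id].append(
                    TrackRecord(job.fly_id, t, det.x, det.y, valid=True)
                )
    return out


def estimate_fbl(detections: Sequence[Detection]) -> float:
    """Fly body length in pixels: the median major-axis extent of detections."""
    if not detections:
        raise ValueError("need at least one detection to estimate FBL")
    return float(np.median([d.major_axis_px for d in detections]))
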