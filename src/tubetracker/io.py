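"""File formats and configuration.

Two text dialects are defined here:

* **Coordinate files** — the tracker's native output: one tab-delimited row
  per 1 Hz tick, an ``(x, y, valid)`` triple per track job, preceded by a
  self-describing ``#``-prefixed header (schema version, job ids, absolute
  start anchor, capture interval).  The layout is versioned because the
  original single-text-file format was never published; floats are written
  with shortest round-trip ``repr`` so read(write(x)) == x bit-exactly.

* **DAM monitor files** — the Trikinetics 32-channel dialect: tab-delimited
  rows of record index, date ("D Mon YY"), time ("HH:MM:SS"), seven status
  fields, then 32 integer channel counts.  Binned tracker output written in
  this dialect is drop-in comparable with real beam-cross monitor files;
  populations larger than 32 flies are split across suffixed files.

All timestamps inside the package are experiment-relative integer seconds;
the one absolute anchor lives in the file headers.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import Calibration, LightSchedule, Rect, TrackRecord, Trajectory
from .tracking import TrackJob

__all__ = [
    "COORD_SCHEMA_VERSION",
    "write_coordinates",
    "read_coordinates",
    "write_dam",
    "read_dam",
    "DamData",
    "Config",
    "load_config",
]

COORD_SCHEMA_VERSION = 1
DAM_CHANNELS = 32
_DEFAULT_ANCHOR = _dt.datetime(2012, 1, 1, 8, 0, 0)

_MONTHS = "Jan Feb Mar Apr May Jun Jul Aug Sep Oct Nov Dec".split()


class FileFormatError(ValueError):
    """Malformed input file; the message carries the offending line number."""


# ---------------------------------------------------------------- coordinates


def _fmt(v: float) -> str:
    return repr(float(v))


def write_coordinates(
    path: str | Path,
    trajectories: list[Trajectory],
    interval_s: int = 1,
    anchor: _dt.datetime = _DEFAULT_ANCHOR,
) -> None:
    """Write 1 Hz coordinates for all flies into a single text file."""
    if not trajectories:
        raise ValueError("nothing to write")
    times = trajectories[0].times()
    for tr in trajectories[1:]:
        if len(tr) != len(times) or (tr.times() != times).any():
            raise ValueError("all trajectories must share one time base")
    ids = [tr.fly_id for tr in trajectories]
    with open(path, "w") as fh:
        fh.write(f"# tubetracker-coords v{COORD_SCHEMA_VERSION}\n")
        fh.write(f"# anchor\t{anchor.isoformat()}\n")
        fh.write(f"# interval_s\t{interval_s}\n")
        fh.write("# jobs\t" + "\t".join(ids) + "\n")
        cols = ["t"]
        for i in ids:
            cols += [f"{i}.x", f"{i}.y", f"{i}.valid"]
        fh.write("\t".join(cols) + "\n")
        for k, t in enumerate(times):
            row = [str(int(t))]
            for tr in trajectories:
                r = tr.records[k]
                row += [_fmt(r.x), _fmt(r.y), "1" if r.valid else "0"]
            fh.write("\t".join(row) + "\n")


def read_coordinates(
    path: str | Path,
    calibrations: dict[str, Calibration] | None = None,
) -> tuple[list[Trajectory], dict]:
    """Parse a coordinate file back into trajectories (lossless round-trip).

    ``calibrations`` optionally attaches a Calibration per fly_id.  Returns
    ``(trajectories, metadata)`` where metadata carries the header fields.
    """
    path = Path(path)
    meta: dict = {}
    ids: list[str] = []
    rows: list[list[str]] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("# tubetracker-coords v"):
        raise FileFormatError(f"{path}:1: missing coordinate-file signature")
    version = int(lines[0].split("v")[-1])
    if version != COORD_SCHEMA_VERSION:
        raise FileFormatError(
            f"{path}:1: unsupported schema version {version} "
            f"(expected {COORD_SCHEMA_VERSION})"
        )
    body_start = None
    for ln, line in enumerate(lines[1:], start=2):
        line = line.rstrip("\n")
        if line.startswith("# "):
            parts = line[2:].split("\t")
            key = parts[0]
            if key == "jobs":
                ids = parts[1:]
            else:
                meta[key] = parts[1] if len(parts) > 1 else ""
        else:
            body_start = ln
            break
    if not ids:
        raise FileFormatError(f"{path}: header declares no jobs")
    meta["jobs"] = ids
    meta["interval_s"] = int(meta.get("interval_s", 1))
    ncol = 1 + 3 * len(ids)
    data_lines = lines[body_start - 1 :] if body_start else []
    # first body line is the column-name row
    for ln, line in enumerate(data_lines[1:], start=(body_start or 0) + 1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != ncol:
            raise FileFormatError(
                f"{path}:{ln}: expected {ncol} columns, got {len(parts)}"
            )
        rows.append(parts)
    trajectories = []
    for j, fly_id in enumerate(ids):
        recs = []
        for parts in rows:
            t = int(parts[0])
            x = float(parts[1 + 3 * j])
            y = float(parts[2 + 3 * j])
            valid = parts[3 + 3 * j] == "1"
            recs.append(TrackRecord(fly_id, t, x, y, valid))
        cal = (calibrations or {}).get(fly_id)
        trajectories.append(Trajectory(fly_id, recs, calibration=cal))
    return trajectories, meta


# ------------------------------------------------------------------- DAM files


@dataclass
class DamData:
    """Counts parsed from one DAM monitor file."""

    counts: np.ndarray  # (n_bins, 32)
    bin_length_s: int
    anchor: _dt.datetime
    channel_ids: list[str] = field(default_factory=list)


def _dam_date(d: _dt.datetime) -> str:
    return f"{d.day} {_MONTHS[d.month - 1]} {d.year % 100:02d}"


def write_dam(
    path: str | Path,
    counts: np.ndarray,
    bin_length_s: int,
    anchor: _dt.datetime = _DEFAULT_ANCHOR,
) -> list[Path]:
    """Write binned counts as Trikinetics-style monitor file(s).

    ``counts`` is (n_bins, n_flies); unused channels are zero-filled and
    populations beyond 32 flies are split across files suffixed _M01, _M02…
    Returns the list of files written.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (bins x flies)")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    n_bins, n_flies = counts.shape
    path = Path(path)
    n_files = max(1, -(-n_flies // DAM_CHANNELS))
    written = []
    for f in range(n_files):
        block = counts[:, f * DAM_CHANNELS : (f + 1) * DAM_CHANNELS]
        full = np.zeros((n_bins, DAM_CHANNELS), dtype=np.int64)
        full[:, : block.shape[1]] = block
        out = (
            path
            if n_files == 1
            else path.with_name(f"{path.stem}_M{f + 1:02d}{path.suffix}")
        )
        with open(out, "w") as fh:
            for i in range(n_bins):
                stamp = anchor + _dt.timedelta(seconds=i * bin_length_s)
                fields = [
                    str(i + 1),
                    _dam_date(stamp),
                    stamp.strftime("%H:%M:%S"),
                    "1",  # monitor status
                    "0", "0", "0", "0", "0", "0",
                ] + [str(int(c)) for c in full[i]]
                fh.write("\t".join(fields) + "\n")
        written.append(out)
    return written


def read_dam(path: str | Path) -> DamData:
    """Parse a Trikinetics-style monitor file into a counts matrix."""
    path = Path(path)
    counts = []
    stamps = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 10 + DAM_CHANNELS:
                raise FileFormatError(
                    f"{path}:{ln}: expected {10 + DAM_CHANNELS} fields, "
                    f"got {len(parts)}"
                )
            day, mon, yy = parts[1].split()
            stamp = _dt.datetime.strptime(
                f"{day} {mon} {yy} {parts[2]}", "%d %b %y %H:%M:%S"
            )
            stamps.append(stamp)
            try:
                counts.append([int(c) for c in parts[10:]])
            except ValueError as e:
                raise FileFormatError(f"{path}:{ln}: bad channel count: {e}")
    if not counts:
        raise FileFormatError(f"{path}: empty monitor file")
    if len(stamps) > 1:
        bin_length = int((stamps[1] - stamps[0]).total_seconds())
    else:
        bin_length = 60
    return DamData(
        counts=np.asarray(counts, dtype=np.int64),
        bin_length_s=bin_length,
        anchor=stamps[0],
    )


# --------------------------------------------------------------------- config


@dataclass
class Config:
    """Run configuration: light schedule, per-fly calibration, thresholds."""

    schedule: LightSchedule
    calibrations: dict[str, Calibration]
    min_fraction: float = 0.5
    max_fraction: float = 1.5
    contrast_threshold: float = 60.0
    min_area: int = 6
    max_area: int = 400
    interval_s: int = 1

    def jobs(self) -> list[TrackJob]:
        return [
            TrackJob(
                fly_id=fid,
                roi=cal.roi,
                contrast_threshold=self.contrast_threshold,
                min_area=self.min_area,
                max_area=self.max_area,
            )
            for fid, cal in self.calibrations.items()
        ]


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML run configuration.

    Rejects overlapping ROIs (each track job must be a discrete area with a
    single fly) and non-positive FBL fractions.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    sched_raw = raw.get("schedule", {})
    schedule = LightSchedule(
        lights_on_zt0=int(sched_raw.get("lights_on_zt0", 0)),
        photoperiod_min=int(sched_raw.get("photoperiod_min", 720)),
        cycle_min=int(sched_raw.get("cycle_min", 1440)),
    )
    thr = raw.get("thresholds", {})
    min_fraction = float(thr.get("min_fraction", 0.5))
    max_fraction = float(thr.get("max_fraction", 1.5))
    if min_fraction <= 0 or max_fraction <= 0:
        raise ValueError("FBL fractions must be positive")
    if min_fraction > max_fraction:
        raise ValueError("min_fraction must not exceed max_fraction")
    trk = raw.get("tracking", {})
    cals: dict[str, Calibration] = {}
    for job in raw.get("jobs", []):
        fid = str(job["fly_id"])
        if fid in cals:
            raise ValueError(f"duplicate fly_id {fid!r}")
        x0, y0, w, h = (int(v) for v in job["roi"])
        roi = Rect(x0, y0, w, h)
        cals[fid] = Calibration(
            fbl_px=float(job.get("fbl_px", 10.0)),
            roi=roi,
            food_end=str(job.get("food_end", "high")),
            beam_x=float(job["beam_x"]) if "beam_x" in job else None,
            tube_length_mm=float(job.get("tube_length_mm", 65.0)),
        )
    ids = list(cals)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if cals[a].roi.overlaps(cals[b].roi):
                raise ValueError(
                    f"jobs {a!r} and {b!r} have overlapping ROIs; each track "
                    "job must be a discrete, non-overlapping area"
                )
    return Config(
        schedule=schedule,
        calibrations=cals,
        min_fraction=min_fraction,
        max_fraction=max_fraction,
        contrast_threshold=float(trk.get("contrast_threshold", 60.0)),
        min_area=int(trk.get("min_area", 6)),
        max_area=int(trk.get("max_area", 400)),
        interval_s=int(trk.get("interval_s", 1)),
    )
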