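import numpy as np
import pytest

from tubetracker import Calibration, LightSchedule, Rect, TrackRecord, Trajectory


@pytest.fixture
def schedule():
    """12:12 LD anchored at experiment start."""
    return LightSchedule(lights_on_zt0=0, photoperiod_min=720, cycle_min=1440)


@pytest.fixture
def calibration():
    """650 px ROI mapping onto a 65 mm tube: 0.1 mm/px, food at high x."""
    return Calibration(
        fbl_px=10.0,
        roi=Rect(0, 0, 650, 50),
        food_end="high",
        beam_x=325.0,
        tube_length_mm=65.0,
    )


def build_trajectory(xs, ys=None, fly_id="f1", calibration=None, valid=None, t0=0):
    """1 Hz trajectory from coordinate arrays (helper shared across tests)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.full_like(xs, 25.0) if ys is None else np.asarray(ys, dtype=float)
    valid = np.ones(len(xs), dtype=bool) if valid is None else np.asarray(valid)
    recs = [
        TrackRecord(fly_id, t0 + i, float(xs[i]), float(ys[i]), bool(valid[i]))
        for i in range(len(xs))
    ]
    return Trajectory(fly_id, recs, calibration=calibration)


@pytest.fixture
def make_traj():
    return build_trajectory
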