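"""Plot rendering: sleep profiles and place-preference heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_sleep_timecourse", "plot_occupancy"]


def plot_sleep_timecourse(
    zt_start_min: np.ndarray,
    sleep_min: np.ndarray,
    out_path: str | Path,
    bin_min: int = 30,
    photoperiod_min: int = 720,
) -> Path:
    """Line plot of sleep minutes per ZT bin, dark phase shaded."""
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(zt_start_min / 60.0, sleep_min, marker="o", ms=3, color="k")
    ax.axvspan(photoperiod_min / 60.0, 24, color="0.85", zorder=0)
    ax.set_xlim(0, 24)
    ax.set_ylim(0, bin_min)
    ax.set_xlabel("ZT (h)")
    ax.set_ylabel(f"sleep (min / {bin_min} min)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_occupancy(
    dwell: np.ndarray,
    out_path: str | Path,
    bin_length_s: int = 60,
) -> Path:
    """Heatmap of dwell time: time on the abscissa, tube section on the
    ordinate with the food-adjacent section (10) at the bottom."""
    fig, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(
        dwell,
        aspect="auto",
        origin="upper",
        cmap="Blues",
        interpolation="nearest",
        extent=(0, dwell.shape[1] * bin_length_s / 3600.0, 10.5, 0.5),
    )
    ax.set_xlabel("time (h)")
    ax.set_ylabel("tube section (10 = food)")
    ax.set_yticks(range(1, 11))
    fig.colorbar(im, ax=ax, label="dwell (s)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
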