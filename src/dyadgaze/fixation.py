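"""Dispersion-threshold (I-DT) fixation detection on 60 Hz gaze streams.

The detector implements the classic I-DT scheme: a temporal window is
initialised to span the minimum fixation duration and grown sample by
sample while its spatial dispersion stays at or below the threshold; a
window that reaches the minimum duration is emitted as a fixation with the
arithmetic-mean centroid of its member samples. Dispersion is measured in
visual degrees using the fixed linear pixel-to-degree scale of the scene
camera (60 deg / 1280 px horizontally, 46 deg / 960 px vertically by
default). Invalid samples (blinks, track loss) split the stream: a
fixation never bridges a gap, and periods of loss are excluded from the
valid-time accounting used later for proportional gaze measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = ["Fixation", "pixels_to_degrees", "detect_fixations",
           "fixations_to_frame"]


@dataclass(frozen=True)
class Fixation:
    """A detected stable-gaze event.

    ``t_start``/``t_end`` are the timestamps (ms) of the first and last
    member samples; ``centroid`` is in scene pixels; ``dispersion`` is in
    degrees under the configured metric; ``frame`` is the scene-frame
    index at the temporal midpoint.
    """

    t_start: float
    t_end: float
    centroid: tuple[float, float]
    dispersion: float
    frame: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def pixels_to_degrees(dx, dy, config: AnalysisConfig | None = None):
    """Convert pixel offsets to visual degrees, per axis (linear scale)."""
    config = config or AnalysisConfig()
    sx, sy = config.deg_per_px
    return np.asarray(dx) * sx, np.asarray(dy) * sy


def _dispersion(xr_deg: float, yr_deg: float, metric: str) -> float:
    if metric == "sum":
        return xr_deg + yr_deg
    return max(xr_deg, yr_deg)


def _idt_run(t: np.ndarray, x: np.ndarray, y: np.ndarray,
             config: AnalysisConfig) -> list[Fixation]:
    """Greedy I-DT over one gap-free run of valid samples."""
    sx, sy = config.deg_per_px
    thresh = config.max_dispersion_deg
    min_dur = config.min_fixation_ms
    metric = config.dispersion_metric
    n = len(t)
    fixations: list[Fixation] = []
    # timing tolerance: a window spanning the minimum duration up to
    # float rounding (timestamps accumulate in ms) still qualifies
    eps = 1e-6
    i = 0
    while i < n:
        # smallest window [i, j] spanning the minimum duration
        j = int(np.searchsorted(t, t[i] + min_dur - eps, side="left"))
        if j >= n:
            break
        xmin = x[i:j + 1].min(); xmax = x[i:j + 1].max()
        ymin = y[i:j + 1].min(); ymax = y[i:j + 1].max()
        if _dispersion((xmax - xmin) * sx, (ymax - ymin) * sy, metric) > thresh:
            i += 1
            continue
        # grow while the dispersion criterion holds
        while j + 1 < n:
            nxmin = min(xmin, x[j + 1]); nxmax = max(xmax, x[j + 1])
            nymin = min(ymin, y[j + 1]); nymax = max(ymax, y[j + 1])
            if _dispersion((nxmax - nxmin) * sx, (nymax - nymin) * sy,
                           metric) > thresh:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        t_mid = 0.5 * (t[i] + t[j])
        fixations.append(Fixation(
            t_start=float(t[i]),
            t_end=float(t[j]),
            centroid=(float(x[i:j + 1].mean()), float(y[i:j + 1].mean())),
            dispersion=float(_dispersion((xmax - xmin) * sx,
                                         (ymax - ymin) * sy, metric)),
            frame=int(t_mid * config.scene_fps / 1000.0),
        ))
        i = j + 1
    return fixations


def detect_fixations(samples: pd.DataFrame,
                     config: AnalysisConfig | None = None,
                     ) -> tuple[list[Fixation], float]:
    """Detect fixations in a time-ordered gaze stream.

    Parameters
    ----------
    samples
        DataFrame with columns ``t_ms``, ``x_px``, ``y_px``, ``valid``
        for one participant x task, ordered by time.
    config
        Analysis settings; defaults match the study configuration.

    Returns
    -------
    fixations, valid_time_ms
        Fixations satisfying both thresholds, time-ordered and
        non-overlapping, and the total time covered by valid samples
        (number of valid samples times the sample period).
    """
    config = config or AnalysisConfig()
    if len(samples) == 0:
        return [], 0.0
    t = np.asarray(samples["t_ms"], dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("gaze samples must be time-ordered")
    x = np.asarray(samples["x_px"], dtype=float)
    y = np.asarray(samples["y_px"], dtype=float)
    valid = np.asarray(samples["valid"], dtype=bool)

    valid_time = float(valid.sum()) * config.sample_period_ms

    fixations: list[Fixation] = []
    # split at invalid samples: a loss period terminates any open window
    idx = np.flatnonzero(valid)
    if len(idx) == 0:
        return [], 0.0
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    for s, e in zip(starts, ends):
        run = idx[s:e + 1]
        fixations.extend(_idt_run(t[run], x[run], y[run], config))
    return fixations, valid_time


def fixations_to_frame(fixations: list[Fixation],
                       participant: str | None = None,
                       task: str | None = None) -> pd.DataFrame:
    """Tabulate fixations (one row each) for serialization."""
    rows = [{
        "t_start_ms": f.t_start, "t_end_ms": f.t_end,
        "duration_ms": f.duration, "x_px": f.centroid[0],
        "y_px": f.centroid[1], "dispersion_deg": f.dispersion,
        "frame": f.frame,
    } for f in fixations]
    df = pd.DataFrame(rows, columns=["t_start_ms", "t_end_ms", "duration_ms",
                                     "x_px", "y_px", "dispersion_deg",
                                     "frame"])
    if participant is not None:
        df.insert(0, "participant", participant)
    if task is not None:
        df.insert(1, "task", task)
    return df
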