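"""Region-of-interest outcome computation.

For every participant x task x speech state, fixations labeled
upper/lower/outside are intersected with the coded speech periods
(durations clipped to period boundaries, which preserves additivity) and
aggregated into the two dependent variables of the ROI analysis:

* ``face_prop`` — face fixation time proportional to valid total fixation
  time within the coded periods (loss periods contribute nothing);
* ``upper_prop`` — upper-face fixation time proportional to face fixation
  time, defined only when there is any face fixation time.

Unclassifiable fixations (no face box near their frame) count as data
loss: they are excluded from the valid fixation time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .speech import SpeechPeriod

__all__ = ["compute_proportions"]

_LABELS = ("upper", "lower", "outside", "unclassifiable")


def _overlaps(starts: np.ndarray, ends: np.ndarray,
              periods: list[tuple[float, float]]) -> np.ndarray:
    """Total overlap of each [start, end] interval with a period set."""
    out = np.zeros(len(starts))
    for p0, p1 in periods:
        out += np.clip(np.minimum(ends, p1) - np.maximum(starts, p0), 0, None)
    return out


def compute_proportions(labeled_fixations: pd.DataFrame,
                        periods: list[SpeechPeriod],
                        gaze: pd.DataFrame | None = None,
                        config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Aggregate labeled fixations into per-cell ROI outcomes.

    Parameters
    ----------
    labeled_fixations
        Columns ``participant``, ``task``, ``t_start_ms``, ``t_end_ms``,
        ``label`` (upper/lower/outside/unclassifiable).
    periods
        Coded speaking/listening periods (see
        :func:`dyadgaze.speech.code_speech_periods`).
    gaze
        Optional raw gaze table (``participant``, ``task``, ``t_ms``,
        ``valid``); when given, per-cell valid time and loss fraction are
        computed from the validity flags, else left as NaN.
    config
        Analysis settings.

    Returns
    -------
    DataFrame with one row per participant x task x speech state:
    ``face_prop``, ``upper_prop``, durations per label, ``period_ms``,
    ``valid_ms``, ``loss_frac``, ``missing`` (True when the cell has no
    valid fixation time and must be excluded listwise downstream).
    """
    config = config or AnalysisConfig()
    by_cell: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    for p in periods:
        by_cell.setdefault((p.participant, p.task, p.role), []).append(
            (p.t_start, p.t_end))

    fix_groups = {k: g for k, g in labeled_fixations.groupby(
        ["participant", "task"], sort=False)} if len(labeled_fixations) else {}
    gaze_groups = {k: g for k, g in gaze.groupby(
        ["participant", "task"], sort=False)} if gaze is not None else {}

    rows = []
    for (pid, task, state), window in sorted(by_cell.items()):
        fx = fix_groups.get((pid, task))
        durations = dict.fromkeys(_LABELS, 0.0)
        if fx is not None and len(fx):
            ov = _overlaps(np.asarray(fx["t_start_ms"], float),
                           np.asarray(fx["t_end_ms"], float), window)
            for label, d in zip(fx["label"], ov):
                durations[str(label)] += float(d)
        face_ms = durations["upper"] + durations["lower"]
        valid_fix_ms = face_ms + durations["outside"]
        face_prop = face_ms / valid_fix_ms if valid_fix_ms > 0 else np.nan
        upper_prop = durations["upper"] / face_ms if face_ms > 0 else np.nan

        period_ms = sum(t1 - t0 for t0, t1 in window)
        valid_ms = np.nan
        loss_frac = np.nan
        gz = gaze_groups.get((pid, task))
        if gz is not None:
            t = np.asarray(gz["t_ms"], float)
            ok = np.asarray(gz["valid"], bool)
            in_window = np.zeros(len(t), bool)
            for t0, t1 in window:
                in_window |= (t >= t0) & (t < t1)
            valid_ms = float((ok & in_window).sum()) * config.sample_period_ms
            loss_frac = 1.0 - valid_ms / period_ms if period_ms > 0 else np.nan

        rows.append({
            "participant": pid, "task": task, "speech_state": state,
            "face_prop": face_prop, "upper_prop": upper_prop,
            "upper_ms": durations["upper"], "lower_ms": durations["lower"],
            "outside_ms": durations["outside"],
            "unclassifiable_ms": durations["unclassifiable"],
            "period_ms": period_ms, "valid_ms": valid_ms,
            "loss_frac": loss_frac,
            "missing": valid_fix_ms == 0,
        })
    return pd.DataFrame(rows)
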