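"""Whole-table pipeline stages gluing the per-stream operations together.

These are the batch entry points used by the CLI, the examples and the
acceptance studies: fixation detection over a multi-participant gaze
table, face-region labeling, ROI outcome computation, per-participant
density-map construction (speaking/listening, collapsed across tasks),
and the end-to-end group permutation analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .density import DensityMap, FaceTemplate, accumulate_density, smooth_map
from .facegeom import classify_fixation
from .fixation import Fixation, detect_fixations, fixations_to_frame
from .permutation import PermutationResult, permutation_test
from .roi import compute_proportions
from .speech import SpeechPeriod, code_speech_periods
from .tables import faceboxes_by_frame

__all__ = ["detect_fixations_table", "label_fixations_table",
           "roi_outcomes", "build_density_maps", "run_permutation_analysis"]


def detect_fixations_table(gaze: pd.DataFrame,
                           config: AnalysisConfig | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detect fixations per participant x task.

    Returns (fixation table, valid-time table with one row per cell).
    """
    config = config or AnalysisConfig()
    fix_parts, valid_rows = [], []
    for (pid, task), g in gaze.groupby(["participant", "task"], sort=True):
        fixations, valid_ms = detect_fixations(g, config)
        fix_parts.append(fixations_to_frame(fixations, pid, task))
        valid_rows.append({"participant": pid, "task": task,
                           "valid_ms": valid_ms})
    fixation_table = (pd.concat(fix_parts, ignore_index=True) if fix_parts
                      else fixations_to_frame([], "", ""))
    return fixation_table, pd.DataFrame(valid_rows)


def label_fixations_table(fixations: pd.DataFrame, face_boxes: pd.DataFrame,
                          config: AnalysisConfig | None = None,
                          ) -> pd.DataFrame:
    """Attach upper/lower/outside/unclassifiable labels to fixations."""
    config = config or AnalysisConfig()
    boxes = faceboxes_by_frame(face_boxes)
    labels = []
    for row in fixations.itertuples(index=False):
        cell_boxes = boxes.get((row.participant, row.task), {})
        fix = Fixation(t_start=row.t_start_ms, t_end=row.t_end_ms,
                       centroid=(row.x_px, row.y_px),
                       dispersion=row.dispersion_deg, frame=int(row.frame))
        region = classify_fixation(fix, cell_boxes, config)
        labels.append(region.value if region is not None else "unclassifiable")
    out = fixations.copy()
    out["label"] = labels
    return out


def roi_outcomes(labeled_fixations: pd.DataFrame, speech_events: pd.DataFrame,
                 gaze: pd.DataFrame | None = None,
                 config: AnalysisConfig | None = None,
                 ) -> tuple[pd.DataFrame, list[SpeechPeriod]]:
    """Code speech periods and compute per-cell ROI outcomes."""
    config = config or AnalysisConfig()
    periods = code_speech_periods(speech_events, config)
    outcomes = compute_proportions(labeled_fixations, periods, gaze, config)
    return outcomes, periods


def build_density_maps(labeled_fixations: pd.DataFrame,
                       face_boxes: pd.DataFrame,
                       periods: list[SpeechPeriod],
                       config: AnalysisConfig | None = None,
                       collapse_tasks: bool = True,
                       ) -> dict[tuple[str, str], DensityMap]:
    """Smoothed unit-mass density maps per participant x speech state.

    On-face fixations are intersected with the coded periods of each
    speech state and, by default, collapsed across tasks. Keys are
    (participant, state).
    """
    config = config or AnalysisConfig()
    template = FaceTemplate.from_config(config)
    boxes = faceboxes_by_frame(face_boxes)
    by_cell: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    for p in periods:
        by_cell.setdefault((p.participant, p.task, p.role), []).append(
            (p.t_start, p.t_end))

    raw: dict[tuple[str, str], np.ndarray] = {}
    seen: set[tuple[str, str]] = set()
    for (pid, task), g in labeled_fixations.groupby(["participant", "task"],
                                                    sort=True):
        for state in ("speaking", "listening"):
            window = by_cell.get((pid, task, state))
            key = (pid, state)
            seen.add(key)
            if not window:
                continue
            t0 = g["t_start_ms"].to_numpy(float)
            t1 = g["t_end_ms"].to_numpy(float)
            overlap = np.zeros(len(g))
            for w0, w1 in window:
                overlap += np.clip(np.minimum(t1, w1) - np.maximum(t0, w0),
                                   0, None)
            sub = g[overlap > 0].copy()
            # deposit weight equal to the within-period portion
            sub["t_end_ms"] = sub["t_start_ms"] + overlap[overlap > 0]
            dmap = accumulate_density(sub, boxes.get((pid, task), {}),
                                      template, participant=pid,
                                      condition=state)
            acc = raw.setdefault(key, np.zeros_like(dmap.values))
            if not dmap.missing:
                acc += dmap.values

    maps: dict[tuple[str, str], DensityMap] = {}
    for key in sorted(seen):
        values = raw.get(key)
        if values is None or values.sum() == 0:
            maps[key] = DensityMap(
                np.zeros((template.height_px, template.width_px)),
                participant=key[0], condition=key[1], missing=True)
        else:
            maps[key] = smooth_map(
                DensityMap(values, participant=key[0], condition=key[1]),
                config, template)
    return maps


def run_permutation_analysis(maps: dict[tuple[str, str], DensityMap],
                             group_of: dict[str, str], state: str,
                             config: AnalysisConfig | None = None,
                             rng=None) -> PermutationResult:
    """Cluster permutation test of the group map difference in one state."""
    config = config or AnalysisConfig()
    selected = [(pid, m) for (pid, st), m in sorted(maps.items())
                if st == state]
    labels = [group_of[pid] for pid, _ in selected]
    return permutation_test([m for _, m in selected], labels, config, rng)
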