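"""Calibration and recovery studies exercising the whole pipeline.

These are the package's own verification experiments: family-wise error
calibration of the cluster permutation test on null cohorts, threshold
contracts of the fixation detector on a constructed stream, the speech
cropping and box re-detection cadence contracts, and end-to-end recovery
of injected effects (a mouth-located group difference; a
listening-vs-speaking face-looking gap). Each study is a deterministic
function of its seed and returns plain numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .density import FaceTemplate
from .facegeom import FaceBox, RedetectSignal, propagate_box
from .fixation import detect_fixations
from .permutation import permutation_test
from .pipeline import (build_density_maps, detect_fixations_table,
                       label_fixations_table, roi_outcomes)
from .speech import code_speech_periods
from .stats import mixed_anova_2x2x2
from .synthetic import (CohortSpec, InjectedEffect, default_profiles,
                        generate_cohort, generate_face_track,
                        generate_null_maps, with_off_face)

__all__ = ["fwer_null_study", "fixation_contract_stream",
           "fixation_contract_summary", "speech_crop_demo",
           "box_propagation_cadence", "cluster_recovery_study",
           "speech_effect_recovery_study"]


# ----------------------------------------------------------------------
# Family-wise error under the null (permutation-test calibration)

def fwer_null_study(n_cohorts: int = 200, n_per_group: int = 14,
                    n_permutations: int = 500, n_fixations: int = 120,
                    seed: int = 0) -> dict:
    """Fraction of null cohorts with any significant cluster.

    Each cohort draws ``2 * n_per_group`` smoothed unit-mass maps from
    one common generating mixture (no group difference), then runs the
    cluster permutation test. Under exchangeability the family-wise rate
    must not exceed the cluster alpha (0.05) beyond binomial error.
    """
    config = AnalysisConfig(n_permutations=n_permutations)
    profile = default_profiles()["western"]
    rng = np.random.default_rng(seed)
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    hits = 0
    for _ in range(n_cohorts):
        maps = generate_null_maps(2 * n_per_group, profile,
                                  n_fixations=n_fixations, rng=rng,
                                  config=config)
        result = permutation_test(maps, labels, config,
                                  rng=int(rng.integers(2 ** 31)))
        hits += bool(result.significant_clusters)
    return {"rate": hits / n_cohorts, "n_cohorts": n_cohorts,
            "n_per_group": n_per_group}


# ----------------------------------------------------------------------
# Fixation-detector threshold contracts

#: stationary-segment durations (ms) interleaved in the contract stream
SEGMENT_DURATIONS_MS = (17.0, 33.0, 50.0, 100.0, 250.0, 500.0)


def fixation_contract_stream(seed: int = 0, n_repeats: int = 100,
                             config: AnalysisConfig | None = None,
                             ) -> pd.DataFrame:
    """Seeded 60 Hz stream of stationary segments split by 500 px jumps.

    Segments of 17-500 ms alternate between two scene anchors more than
    500 px apart, each with small positional jitter (well inside the
    dispersion threshold) plus a per-segment placement jitter.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    dt = config.sample_period_ms
    anchors = [np.array([320.0, 250.0]), np.array([880.0, 700.0])]
    rows_t, rows_x, rows_y = [], [], []
    t = 0.0
    flip = 0
    for _ in range(n_repeats):
        for dur in SEGMENT_DURATIONS_MS:
            n = int(round(dur / dt)) + 1
            base = anchors[flip] + rng.uniform(-40.0, 40.0, 2)
            jit = np.clip(rng.normal(0.0, 1.5, (n, 2)), -3.0, 3.0)
            for k in range(n):
                rows_t.append(t)
                rows_x.append(base[0] + jit[k, 0])
                rows_y.append(base[1] + jit[k, 1])
                t += dt
            flip = 1 - flip
    return pd.DataFrame({"t_ms": rows_t, "x_px": rows_x, "y_px": rows_y,
                         "valid": True})


def fixation_contract_summary(seed: int = 0,
                              config: AnalysisConfig | None = None) -> dict:
    """Min duration and max dispersion over all detected fixations."""
    config = config or AnalysisConfig()
    stream = fixation_contract_stream(seed, config=config)
    fixations, _ = detect_fixations(stream, config)
    return {"min_duration_ms": min(f.duration for f in fixations),
            "max_dispersion_deg": max(f.dispersion for f in fixations),
            "n_fixations": len(fixations)}


# ----------------------------------------------------------------------
# Speech cropping contract

def speech_crop_demo(config: AnalysisConfig | None = None) -> dict:
    """Longest coded speaking period from 45 s of uninterrupted speech."""
    config = config or AnalysisConfig()
    events = pd.DataFrame([
        {"participant": "P1", "task": "introduction", "event": "speech_on",
         "role": "participant", "t_ms": 0.0},
        {"participant": "P1", "task": "introduction", "event": "speech_off",
         "role": "participant", "t_ms": 45_000.0}])
    periods = code_speech_periods(events, config)
    longest = max(p.duration for p in periods)
    return {"longest_speaking_s": longest / 1000.0, "n_periods": len(periods)}


# ----------------------------------------------------------------------
# Box-propagation cadence contract

def box_propagation_cadence(n_frames: int = 600, seed: int = 0,
                            config: AnalysisConfig | None = None) -> dict:
    """Frames advanced from one detection before mandatory re-detection.

    A noiseless synthetic track (30 points per frame, no dropout) is
    propagated frame by frame from frame 0 until the stage refuses.
    """
    config = config or AnalysisConfig()
    track = generate_face_track(n_frames, motion_amplitude_px=25.0,
                                seed=seed, config=config)
    box = track.boxes[0]
    advanced = 0
    for k in range(1, n_frames):
        out = propagate_box(track.points[k - 1], track.points[k], box,
                            frames_since_detection=k - 1, config=config)
        if isinstance(out, RedetectSignal):
            break
        box = out
        advanced += 1
    return {"frames_advanced": advanced, "n_frames": n_frames}


# ----------------------------------------------------------------------
# End-to-end recovery of injected effects

def _run_cohort_to_maps(cohort, config):
    fixations, _ = detect_fixations_table(cohort.gaze, config)
    labeled = label_fixations_table(fixations, cohort.face_boxes, config)
    outcomes, periods = roi_outcomes(labeled, cohort.speech_events,
                                     cohort.gaze, config)
    maps = build_density_maps(labeled, cohort.face_boxes, periods, config)
    return labeled, outcomes, maps


def cluster_recovery_study(n_replicates: int = 50, n_per_group: int = 14,
                           session_duration_s: float = 30.0,
                           effect_weight: float = 0.25,
                           n_permutations: int = 500,
                           seed: int = 0) -> dict:
    """Detection and localization rate for an injected mouth effect.

    Each replicate generates a full cohort (group B carries an extra
    mouth-located mixture component), runs gaze through fixation
    detection, labeling, density mapping and the cluster permutation
    test on the listening-state maps, and scores a success when some
    significant cluster's centroid lies within 2 degrees of the injected
    center.
    """
    config = AnalysisConfig(n_permutations=n_permutations)
    template = FaceTemplate.from_config(config)
    base = default_profiles()["eastern"]
    effect = InjectedEffect(center_deg=(5.5, 9.8), weight=effect_weight,
                            spread_deg=1.0)
    rng = np.random.default_rng(seed)
    detected = localized = 0
    for _ in range(n_replicates):
        spec = CohortSpec(n_per_group=n_per_group,
                          session_duration_s=session_duration_s,
                          loss_rate=0.08, motion_amplitude_px=30.0,
                          seed=int(rng.integers(2 ** 31)))
        cohort = generate_cohort(spec, base, base, injected_effect=effect,
                                 config=config)
        _, _, maps = _run_cohort_to_maps(cohort, config)
        selected = [(pid, m) for (pid, state), m in sorted(maps.items())
                    if state == "listening"]
        result = permutation_test([m for _, m in selected],
                                  [cohort.group_of[pid]
                                   for pid, _ in selected],
                                  config, rng=int(rng.integers(2 ** 31)))
        sig = result.significant_clusters
        detected += bool(sig)
        cx = effect.center_deg[0] / template.deg_per_px
        cy = effect.center_deg[1] / template.deg_per_px
        for c in sig:
            centroid = c.pixels.mean(axis=0)  # (row, col)
            dist_deg = np.hypot((centroid[1] - cx) * template.deg_per_px,
                                (centroid[0] - cy) * template.deg_per_px)
            if dist_deg <= 2.0:
                localized += 1
                break
    return {"detection_rate": detected / n_replicates,
            "localization_rate": localized / n_replicates,
            "n_replicates": n_replicates, "n_per_group": n_per_group}


def speech_effect_recovery_study(n_replicates: int = 50,
                                 n_per_group: int = 25,
                                 session_duration_s: float = 30.0,
                                 off_face_speaking: float = 0.45,
                                 off_face_listening: float = 0.15,
                                 seed: int = 0) -> dict:
    """Power of the Speech main effect under a face-looking gap.

    Cohorts are generated with more face-directed gaze while listening
    than while speaking (off-face weight 0.15 vs 0.45); each replicate
    runs the full ROI pipeline and the 2x2x2 mixed ANOVA on proportional
    face fixation time, scoring the Speech main effect at alpha = 0.05.
    """
    config = AnalysisConfig()
    base = default_profiles()["western"]
    profiles = {"speaking": with_off_face(base, off_face_speaking),
                "listening": with_off_face(base, off_face_listening)}
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        spec = CohortSpec(n_per_group=n_per_group,
                          session_duration_s=session_duration_s,
                          loss_rate=0.08, motion_amplitude_px=30.0,
                          seed=int(rng.integers(2 ** 31)))
        cohort = generate_cohort(spec, profiles, profiles, config=config)
        fixations, _ = detect_fixations_table(cohort.gaze, config)
        labeled = label_fixations_table(fixations, cohort.face_boxes, config)
        outcomes, _ = roi_outcomes(labeled, cohort.speech_events,
                                   cohort.gaze, config)
        table = mixed_anova_2x2x2(
            outcomes, "face_prop",
            cohort.traits.set_index("participant")["group"])
        p = float(table.loc[table["effect"] == "Speech", "p"].iloc[0])
        hits += p < 0.05
    return {"significant_rate": hits / n_replicates,
            "n_replicates": n_replicates, "n_per_group": n_per_group}
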