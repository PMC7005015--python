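"""Synthetic two-group cohorts for the full pipeline.

The study's raw scene videos are not public, so every downstream stage is
driven by this generator. It emulates, with known ground truth:

* smooth head-motion-driven face-box movement as a per-frame similarity
  transform of a base face quadrilateral, with exact point
  correspondences (face-anchored points under the same transform) and a
  dropout schedule to exercise the minimum-point re-detection rule;
* 60 Hz gaze streams synthesized as alternating fixation/saccade
  segments (not white noise), so the dispersion-based detector has true
  positives — fixations sit on a mixture of face-template components
  (eyes/nasion/mouth) or off the face, saccades are 1-3 sample ballistic
  jumps;
* blinks/track loss as contiguous runs (two-state Markov chain with
  geometric run lengths), matching loss from smiling/occlusion episodes
  rather than i.i.d. sample drops;
* speech annotations with alternating speaker turns;
* AQ and LSAS trait scores from group-specific truncated normals, with
  an optional coupling between a participant's latent gaze tendency and
  the trait scores so the correlation stage has a recoverable signal.

All outputs are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .density import DensityMap, FaceTemplate, forward_map, smooth_map
from .errors import InvalidArgumentError
from .facegeom import FaceBox, apply_transform

__all__ = ["CohortSpec", "GazeProfile", "GroundTruth", "FaceTrack",
           "SpeechSchedule", "InjectedEffect", "SyntheticCohort",
           "generate_face_track", "generate_session", "generate_cohort",
           "make_speech_schedule", "default_profiles", "with_off_face",
           "sample_template_points", "generate_null_maps"]

#: template-frame midline (deg): on-face points above are "upper"
_MIDLINE_DEG = 7.0


@dataclass(frozen=True)
class CohortSpec:
    """Study-level parameters of a synthetic cohort."""

    n_per_group: int = 14
    tasks: tuple[str, ...] = ("introduction", "storytelling")
    session_duration_s: float = 60.0
    loss_rate: float = 0.08
    motion_amplitude_px: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise InvalidArgumentError("n_per_group must be >= 2")
        if self.session_duration_s <= 0:
            raise InvalidArgumentError("session_duration_s must be > 0")
        if not 0 <= self.loss_rate < 1:
            raise InvalidArgumentError("loss_rate must be in [0, 1)")


@dataclass(frozen=True)
class GazeProfile:
    """Spatial gaze-generating mixture on the face template.

    ``components`` are ``((cx_deg, cy_deg), spread_deg, weight)`` tuples
    in template degrees (origin top-left, 11 x 14 extent); weights plus
    ``off_face_weight`` must sum to one.
    """

    components: tuple = ()
    off_face_weight: float = 0.0
    fixation_duration_ms: tuple[float, float] = (300.0, 120.0)
    saccade_rate: float = 3.0

    def __post_init__(self):
        total = self.off_face_weight + sum(w for _, _, w in self.components)
        if any(w < 0 for _, _, w in self.components) or self.off_face_weight < 0:
            raise InvalidArgumentError("mixture weights must be >= 0")
        if abs(total - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"weights must sum to 1 with off_face_weight (got {total})")
        if any(s <= 0 for _, s, _ in self.components):
            raise InvalidArgumentError("component spreads must be > 0")
        if self.saccade_rate <= 0:
            raise InvalidArgumentError("saccade_rate must be > 0")


def with_off_face(profile: GazeProfile, off_face_weight: float) -> GazeProfile:
    """Rescale a profile's on-face weights to a new off-face fraction."""
    on = sum(w for _, _, w in profile.components)
    if on <= 0:
        raise InvalidArgumentError("profile has no on-face components")
    scale = (1.0 - off_face_weight) / on
    comps = tuple((c, s, w * scale) for c, s, w in profile.components)
    return replace(profile, components=comps, off_face_weight=off_face_weight)


def default_profiles() -> dict[str, GazeProfile]:
    """Two literature-plausible spatial profiles.

    ``western``: eyes plus pronounced mouth scanning; ``eastern``: eyes
    and central/nasion scanning — the two group-specific densities the
    cohort generator contrasts.
    """
    eyes_l, eyes_r = (3.5, 4.2), (7.5, 4.2)
    nasion, mouth = (5.5, 5.2), (5.5, 9.8)
    western = GazeProfile(components=((eyes_l, 1.2, 0.18),
                                      (eyes_r, 1.2, 0.18),
                                      (mouth, 1.3, 0.34)),
                          off_face_weight=0.30)
    eastern = GazeProfile(components=((eyes_l, 1.2, 0.22),
                                      (eyes_r, 1.2, 0.22),
                                      (nasion, 1.3, 0.26)),
                          off_face_weight=0.30)
    return {"western": western, "eastern": eastern}


@dataclass(frozen=True)
class InjectedEffect:
    """Extra mixture component injected into group B only."""

    center_deg: tuple[float, float] = (5.5, 9.8)  # mouth region
    weight: float = 0.25
    spread_deg: float = 1.0


@dataclass
class GroundTruth:
    """What the generator actually produced, for verification."""

    true_fixations: list = field(default_factory=list)
    true_region_labels: list = field(default_factory=list)
    true_speech_periods: list = field(default_factory=list)
    injected_effect: InjectedEffect | None = None


@dataclass
class FaceTrack:
    """Per-frame boxes, correspondences and the generating transforms."""

    boxes: list[FaceBox]
    points: list[np.ndarray]       # per-frame (k, 2) correspondences
    transforms: list[np.ndarray]   # per-frame 2x3, frame 0 -> frame k
    anchors: np.ndarray            # frame-0 anchor points

    @property
    def n_frames(self) -> int:
        return len(self.boxes)

    def boxes_by_frame(self) -> dict[int, FaceBox]:
        return {b.frame: b for b in self.boxes}


@dataclass
class SpeechSchedule:
    """Alternating speaker turns: (state, t_start_ms, t_end_ms)."""

    turns: list[tuple[str, float, float]]

    def state_at(self, t_ms: float) -> str | None:
        for state, t0, t1 in self.turns:
            if t0 <= t_ms < t1:
                return state
        return None

    def events_frame(self, participant: str, task: str) -> pd.DataFrame:
        rows = []
        for state, t0, t1 in self.turns:
            role = "participant" if state == "speaking" else "partner"
            rows.append({"participant": participant, "task": task,
                         "event": "speech_on", "role": role, "t_ms": t0})
            rows.append({"participant": participant, "task": task,
                         "event": "speech_off", "role": role, "t_ms": t1})
        return pd.DataFrame(rows).sort_values(
            "t_ms", kind="stable", ignore_index=True)


# ----------------------------------------------------------------------
# Face track generation

def _base_box(config: AnalysisConfig) -> np.ndarray:
    """Base face quadrilateral: the 11 x 14 deg face centred in the scene."""
    dx, dy = config.deg_per_px
    w = config.face_extent_deg[0] / dx
    h = config.face_extent_deg[1] / dy
    cx, cy = (config.scene_resolution_px[0] / 2.0,
              config.scene_resolution_px[1] / 2.0)
    return np.array([[cx - w / 2, cy - h / 2], [cx + w / 2, cy - h / 2],
                     [cx + w / 2, cy + h / 2], [cx - w / 2, cy + h / 2]])


def _smooth_noise(n: int, rng: np.random.Generator,
                  smooth_frames: int = 24) -> np.ndarray:
    """Zero-mean smooth random walk normalized to unit max amplitude."""
    steps = rng.standard_normal(n)
    walk = np.cumsum(steps)
    kernel = np.ones(smooth_frames) / smooth_frames
    walk = np.convolve(walk, kernel, mode="same")
    walk -= walk[0]
    peak = np.abs(walk).max()
    return walk / peak if peak > 0 else walk


def generate_face_track(n_frames: int, motion_amplitude_px: float = 40.0,
                        dropout_schedule: np.ndarray | None = None,
                        seed: int = 0,
                        config: AnalysisConfig | None = None,
                        n_anchor_points: int = 30) -> FaceTrack:
    """Generate a smoothly moving face box with point correspondences.

    Motion is a per-frame similarity transform (smooth translation up to
    ``motion_amplitude_px``, plus small rotation and scale oscillation
    proportional to it). ``dropout_schedule`` gives the number of
    correspondences available at each frame (default: all anchors).
    Correspondences are exact images of the frame-0 anchor points under
    the frame's transform; zero amplitude yields identical frames.
    """
    if n_frames < 1:
        raise InvalidArgumentError("n_frames must be >= 1")
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    base = _base_box(config)
    center = base.mean(axis=0)

    # anchor grid strictly inside the face box
    gx = np.linspace(0.15, 0.85, 6)
    gy = np.linspace(0.15, 0.85, 5)
    uv = np.array([(u, v) for v in gy for u in gx])[:n_anchor_points]
    w_vec = base[1] - base[0]
    h_vec = base[3] - base[0]
    anchors = base[0] + uv[:, :1] * w_vec + uv[:, 1:] * h_vec

    if motion_amplitude_px > 0:
        tx = _smooth_noise(n_frames, rng) * motion_amplitude_px
        ty = _smooth_noise(n_frames, rng) * motion_amplitude_px
        rot = _smooth_noise(n_frames, rng) * (motion_amplitude_px / 2000.0)
        scale = 1.0 + _smooth_noise(n_frames, rng) * (motion_amplitude_px / 4000.0)
    else:
        tx = ty = rot = np.zeros(n_frames)
        scale = np.ones(n_frames)

    if dropout_schedule is None:
        dropout_schedule = np.full(n_frames, len(anchors), dtype=int)
    dropout_schedule = np.asarray(dropout_schedule, dtype=int)
    if len(dropout_schedule) != n_frames:
        raise InvalidArgumentError("dropout_schedule must have n_frames entries")

    boxes, points, transforms = [], [], []
    for k in range(n_frames):
        c, s = np.cos(rot[k]), np.sin(rot[k])
        A = scale[k] * np.array([[c, -s], [s, c]])
        t = center - A @ center + np.array([tx[k], ty[k]])
        T = np.column_stack([A, t])
        transforms.append(T)
        # similarity images of the (validated) base stay convex
        boxes.append(FaceBox(frame=k, vertices=apply_transform(T, base),
                             source="detected" if k == 0 else "propagated",
                             check=(k == 0)))
        points.append(apply_transform(T, anchors)[:dropout_schedule[k]])
    return FaceTrack(boxes=boxes, points=points, transforms=transforms,
                     anchors=anchors)


# ----------------------------------------------------------------------
# Speech schedules

def make_speech_schedule(duration_s: float, seed: int = 0,
                         mean_turn_s: float = 14.0) -> SpeechSchedule:
    """Alternating participant/partner speaking turns filling a session."""
    rng = np.random.default_rng(seed)
    turns = []
    t = 0.0
    state = "speaking" if rng.random() < 0.5 else "listening"
    end = duration_s * 1000.0
    while t < end:
        dur = max(3000.0, rng.normal(mean_turn_s * 1000.0,
                                     mean_turn_s * 300.0))
        t1 = min(t + dur, end)
        turns.append((state, t, t1))
        t = t1
        state = "listening" if state == "speaking" else "speaking"
    return SpeechSchedule(turns)


# ----------------------------------------------------------------------
# Session generation

def _template_deg_to_scene(pt_deg: np.ndarray, box: FaceBox,
                           template: FaceTemplate) -> np.ndarray:
    return forward_map(np.asarray(pt_deg) / template.deg_per_px, box, template)


def _draw_fixation_target(profile: GazeProfile, rng: np.random.Generator,
                          template: FaceTemplate, config: AnalysisConfig):
    """Returns (template_pt_deg | None, label); None means off-face."""
    weights = [w for _, _, w in profile.components] + [profile.off_face_weight]
    k = rng.choice(len(weights), p=np.asarray(weights) / sum(weights))
    if k == len(profile.components):
        return None, "off"
    center, spread, _ = profile.components[k]
    wd, hd = template.extent_deg
    pt = rng.normal(center, spread)
    pt = np.clip(pt, [0.25, 0.25], [wd - 0.25, hd - 0.25])
    return pt, ("upper" if pt[1] < _MIDLINE_DEG else "lower")


def _off_face_point(box: FaceBox, rng: np.random.Generator,
                    config: AnalysisConfig) -> np.ndarray:
    from .facegeom import Region, classify_point
    res = config.scene_resolution_px
    for _ in range(200):
        p = rng.uniform([10, 10], [res[0] - 10, res[1] - 10])
        if classify_point(p, box) is Region.OUTSIDE:
            return p
    return np.array([10.0, 10.0])


def generate_session(face_track: FaceTrack,
                     profile: GazeProfile | dict[str, GazeProfile],
                     speech_schedule: SpeechSchedule | None = None,
                     loss_rate: float = 0.0,
                     seed: int = 0,
                     config: AnalysisConfig | None = None,
                     ) -> tuple[pd.DataFrame, GroundTruth]:
    """Synthesize one participant x task gaze stream over a face track.

    Returns a 60 Hz gaze table (``t_ms``, ``x_px``, ``y_px``, ``valid``)
    and the generating ground truth. ``profile`` may be a single
    :class:`GazeProfile` or a dict keyed by speech state (``speaking`` /
    ``listening``) to condition gaze on the schedule.
    """
    config = config or AnalysisConfig()
    if face_track.n_frames == 0:
        raise InvalidArgumentError("face_track is empty")
    if not 0 <= loss_rate < 1:
        raise InvalidArgumentError("loss_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    template = FaceTemplate.from_config(config)
    duration_ms = face_track.n_frames / config.scene_fps * 1000.0
    dt = config.sample_period_ms
    n_samples = int(np.floor(duration_ms / dt))
    t = np.arange(n_samples) * dt
    boxes = face_track.boxes

    def profile_at(t_ms: float) -> GazeProfile:
        if isinstance(profile, dict):
            state = (speech_schedule.state_at(t_ms)
                     if speech_schedule is not None else None)
            return profile.get(state) or next(iter(profile.values()))
        return profile

    x = np.empty(n_samples)
    y = np.empty(n_samples)
    truth = GroundTruth(true_speech_periods=(
        list(speech_schedule.turns) if speech_schedule else []))

    jitter_px = 0.02 / np.mean(config.deg_per_px)
    i = 0
    pending: tuple | None = None  # target handed over from the saccade

    def draw_anchor(sample_idx: int):
        prof = profile_at(t[sample_idx])
        frame = min(int(t[sample_idx] * config.scene_fps / 1000.0),
                    face_track.n_frames - 1)
        box = boxes[frame]
        target_deg, label = _draw_fixation_target(prof, rng, template, config)
        anchor = (_off_face_point(box, rng, config) if target_deg is None
                  else _template_deg_to_scene(target_deg, box, template))
        return target_deg, label, anchor

    while i < n_samples:
        prof = profile_at(t[i])
        mean_ms, sd_ms = prof.fixation_duration_ms
        dur = max(80.0, rng.normal(mean_ms, sd_ms))
        n_fix = min(max(3, int(round(dur / dt))), n_samples - i)
        target_deg, label, anchor = pending or draw_anchor(i)
        pending = None
        pts = anchor + rng.normal(0.0, jitter_px, size=(n_fix, 2))
        x[i:i + n_fix] = pts[:, 0]
        y[i:i + n_fix] = pts[:, 1]
        truth.true_fixations.append({
            "t_start": float(t[i]), "t_end": float(t[i + n_fix - 1]),
            "template_deg": (None if target_deg is None
                             else tuple(target_deg)),
        })
        truth.true_region_labels.append("off" if label == "off" else label)
        i += n_fix
        if i >= n_samples:
            break
        # ballistic saccade: 1-3 samples toward the next fixation target,
        # which then seeds the next fixation
        n_sac = min(int(rng.integers(1, 4)), n_samples - i)
        pending = draw_anchor(min(i + n_sac, n_samples - 1))
        frac = (np.arange(1, n_sac + 1) / (n_sac + 1))[:, None]
        sac = pts[-1] * (1 - frac) + pending[2] * frac
        x[i:i + n_sac] = sac[:, 0]
        y[i:i + n_sac] = sac[:, 1]
        i += n_sac

    # contiguous loss runs: two-state Markov chain, mean run 6 samples
    valid = np.ones(n_samples, dtype=bool)
    if loss_rate > 0:
        p_recover = 1.0 / 6.0
        p_drop = loss_rate * p_recover / (1.0 - loss_rate)
        state = rng.random() >= loss_rate  # True = valid
        for k in range(n_samples):
            valid[k] = state
            state = (rng.random() >= p_drop) if state \
                else (rng.random() < p_recover)
        x[~valid] = np.nan
        y[~valid] = np.nan

    gaze = pd.DataFrame({"t_ms": t, "x_px": x, "y_px": y, "valid": valid})
    return gaze, truth


# ----------------------------------------------------------------------
# Cohorts

@dataclass
class SyntheticCohort:
    gaze: pd.DataFrame
    face_boxes: pd.DataFrame
    speech_events: pd.DataFrame
    traits: pd.DataFrame
    ground_truth: dict
    tracks: dict
    schedules: dict
    group_of: dict

    @property
    def participants(self) -> list[str]:
        return sorted(self.group_of)


#: trait-score distributions per group: (mean, sd, lower, upper), chosen
#: to span the range of published cross-cultural adult samples
TRAIT_DISTRIBUTIONS = {
    "A": {"aq": (14.0, 6.28, 0, 50), "lsas": (36.45, 16.32, 0, 144)},
    "B": {"aq": (21.59, 8.65, 0, 50), "lsas": (48.19, 21.07, 0, 144)},
}


def _apply_effect(profile: GazeProfile,
                  effect: InjectedEffect | None) -> GazeProfile:
    """Inject an extra on-face component of absolute weight
    ``effect.weight``, shrinking the existing on-face components and
    leaving the off-face fraction unchanged."""
    if effect is None:
        return profile
    off = profile.off_face_weight
    on = 1.0 - off
    if effect.weight >= on:
        raise InvalidArgumentError("injected weight exceeds on-face mass")
    scale = (on - effect.weight) / on
    comps = tuple((c, s, w * scale) for c, s, w in profile.components)
    comps += ((tuple(effect.center_deg), effect.spread_deg, effect.weight),)
    return replace(profile, components=comps, off_face_weight=off)


def generate_cohort(spec: CohortSpec,
                    profile_group_a: GazeProfile | dict[str, GazeProfile],
                    profile_group_b: GazeProfile | dict[str, GazeProfile],
                    injected_effect: InjectedEffect | None = None,
                    trait_coupling: float = 0.0,
                    config: AnalysisConfig | None = None) -> SyntheticCohort:
    """Generate a balanced two-group, multi-task cohort.

    With ``injected_effect=None`` and identical profiles the cohort is a
    null cohort: group labels are exchangeable by construction. An
    injected effect adds a mixture component (location and magnitude as
    given) to group B only. ``trait_coupling`` couples a per-participant
    latent gaze tendency (which shifts that participant's off-face
    weight) into the AQ/LSAS scores, giving the correlation stage a
    recoverable signal.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.session_duration_s * config.scene_fps))

    gaze_parts, box_parts, speech_parts, trait_rows = [], [], [], []
    ground_truth, tracks, schedules, group_of = {}, {}, {}, {}

    for group, base_profile in (("A", profile_group_a),
                                ("B", profile_group_b)):
        for j in range(spec.n_per_group):
            pid = f"{group}{j + 1:02d}"
            group_of[pid] = group
            latent = float(rng.standard_normal())
            for trait in ("aq", "lsas"):
                mu, sd, lo, hi = TRAIT_DISTRIBUTIONS[group][trait]
                score = rng.normal(mu, sd) + trait_coupling * sd * latent
                trait_rows.append({"participant": pid, "group": group,
                                   "trait": trait,
                                   "score": float(np.clip(score, lo, hi))})
            for task in spec.tasks:
                child = int(rng.integers(0, 2 ** 31 - 1))
                track = generate_face_track(
                    n_frames, spec.motion_amplitude_px, seed=child,
                    config=config)
                schedule = make_speech_schedule(
                    spec.session_duration_s, seed=child + 1)
                prof = base_profile
                if group == "B" and injected_effect is not None:
                    if isinstance(prof, dict):
                        prof = {k: _apply_effect(v, injected_effect)
                                for k, v in prof.items()}
                    else:
                        prof = _apply_effect(prof, injected_effect)
                if trait_coupling != 0.0:
                    shift = float(np.clip(0.08 * latent, -0.15, 0.15))

                    def _shifted(p: GazeProfile) -> GazeProfile:
                        off = float(np.clip(p.off_face_weight + shift,
                                            0.0, 0.9))
                        return with_off_face(p, off)

                    prof = ({k: _shifted(v) for k, v in prof.items()}
                            if isinstance(prof, dict) else _shifted(prof))
                gaze, truth = generate_session(
                    track, prof, schedule, spec.loss_rate,
                    seed=child + 2, config=config)
                truth.injected_effect = (injected_effect
                                         if group == "B" else None)
                gaze.insert(0, "participant", pid)
                gaze.insert(1, "task", task)
                gaze_parts.append(gaze)
                box_rows = pd.DataFrame({
                    "participant": pid, "task": task,
                    "frame": [b.frame for b in track.boxes],
                    **{f"{c}_{corner}": [b.vertices[ci, xi]
                                         for b in track.boxes]
                       for ci, corner in enumerate(("tl", "tr", "br", "bl"))
                       for xi, c in enumerate(("x", "y"))},
                })
                box_parts.append(box_rows)
                speech_parts.append(schedule.events_frame(pid, task))
                ground_truth[(pid, task)] = truth
                tracks[(pid, task)] = track
                schedules[(pid, task)] = schedule

    traits = pd.DataFrame(trait_rows).pivot_table(
        index=["participant", "group"], columns="trait",
        values="score").reset_index()
    traits.columns.name = None
    return SyntheticCohort(
        gaze=pd.concat(gaze_parts, ignore_index=True),
        face_boxes=pd.concat(box_parts, ignore_index=True),
        speech_events=pd.concat(speech_parts, ignore_index=True),
        traits=traits[["participant", "group", "aq", "lsas"]],
        ground_truth=ground_truth, tracks=tracks, schedules=schedules,
        group_of=group_of)


# ----------------------------------------------------------------------
# Direct map-level sampling (for permutation-test calibration studies)

def sample_template_points(profile: GazeProfile, n: int,
                           rng: np.random.Generator,
                           template: FaceTemplate | None = None,
                           ) -> np.ndarray:
    """Draw n on-face fixation locations (template px) from the mixture.

    Off-face weight is ignored (the draws condition on being on-face).
    """
    template = template or FaceTemplate()
    weights = np.array([w for _, _, w in profile.components], float)
    weights /= weights.sum()
    ks = rng.choice(len(weights), size=n, p=weights)
    centers = np.array([c for c, _, _ in profile.components], float)
    spreads = np.array([s for _, s, _ in profile.components], float)
    pts = rng.normal(centers[ks], spreads[ks, None])
    wd, hd = template.extent_deg
    pts = np.clip(pts, [0.0, 0.0], [wd - 1e-9, hd - 1e-9])
    return pts / template.deg_per_px


def generate_null_maps(n_maps: int, profile: GazeProfile,
                       n_fixations: int = 120,
                       rng: np.random.Generator | int = 0,
                       config: AnalysisConfig | None = None,
                       ) -> list[DensityMap]:
    """Smoothed unit-mass maps drawn from one common generating mixture.

    Each map deposits ``n_fixations`` duration-weighted fixations sampled
    from ``profile`` and is then smoothed and normalized — the map-level
    null used to calibrate the permutation test's family-wise error.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(rng)
    template = FaceTemplate.from_config(config)
    maps = []
    mean_ms, sd_ms = profile.fixation_duration_ms
    for m in range(n_maps):
        pts = sample_template_points(profile, n_fixations, rng, template)
        durs = np.maximum(80.0, rng.normal(mean_ms, sd_ms, n_fixations))
        grid = np.zeros((template.height_px, template.width_px))
        ix = np.minimum(pts[:, 0].astype(int), template.width_px - 1)
        iy = np.minimum(pts[:, 1].astype(int), template.height_px - 1)
        np.add.at(grid, (iy, ix), durs)
        maps.append(smooth_map(DensityMap(grid, participant=f"S{m:03d}"),
                               config, template))
    return maps
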