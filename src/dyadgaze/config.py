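"""Analysis configuration.

Every numeric constant used by the pipeline lives here, with defaults
matching the dyadic head-mounted eye-tracking recording setup the
pipeline targets: glasses sampling gaze at 60 Hz against a 24 fps scene
camera (1280 x 960 px,
60 x 46 degree field of view), I-DT fixation thresholds of 50 ms minimum
duration and 0.5 degree maximum dispersion, a 30 s speech cap with a 20 s
interruption rule, KLT-style box propagation limits (15 points, 150
frames), an 11 x 14 degree face template, a 2 degree Gaussian smoothing
kernel, and cluster-based permutation inference (cluster-forming p = 0.01,
10,000 iterations, family-wise alpha = 0.05).

Coordinate conventions (the pipeline's own, since eye-tracker exports
vary): scene pixels are 0-based with the origin at the top-left, x
rightward, y downward; timestamps are float64 milliseconds; the scene
frame holding time t is ``floor(t_ms * scene_fps / 1000)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidArgumentError

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    # Recording geometry
    sampling_rate_hz: float = 60.0
    scene_fps: float = 24.0
    scene_resolution_px: tuple[int, int] = (1280, 960)
    scene_fov_deg: tuple[float, float] = (60.0, 46.0)

    # Fixation detection (I-DT)
    min_fixation_ms: float = 50.0
    max_dispersion_deg: float = 0.5
    #: "max" = larger side of the window bounding box in degrees;
    #: "sum" = x-range + y-range (alternative vendor convention).
    dispersion_metric: str = "max"

    # Speech coding
    speech_crop_s: float = 30.0
    interruption_min_s: float = 20.0

    # Face-box propagation
    min_track_points: int = 15
    max_track_frames: int = 150
    #: transform fitted to point correspondences: "similarity" (4 dof) or
    #: "affine" (6 dof)
    transform_family: str = "similarity"
    #: how far (in scene frames) to search for a face box when classifying
    #: a fixation whose own frame has none
    box_gap_tolerance_frames: int = 6

    # Face template and density maps
    face_extent_deg: tuple[float, float] = (11.0, 14.0)
    template_px: tuple[int, int] = (110, 140)
    kernel_width_deg: float = 2.0
    #: False: the kernel width is the Gaussian sigma; True: it is the FWHM
    kernel_width_is_fwhm: bool = False
    #: "fixation": deposit fixation duration at the remapped centroid;
    #: "sample": deposit one sample period per remapped valid gaze sample
    deposit_mode: str = "fixation"

    # Cluster-based permutation test
    cluster_forming_p: float = 0.01
    n_permutations: int = 10_000
    cluster_alpha: float = 0.05
    connectivity: int = 8

    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "sampling_rate_hz": self.sampling_rate_hz,
            "scene_fps": self.scene_fps,
            "min_fixation_ms": self.min_fixation_ms,
            "max_dispersion_deg": self.max_dispersion_deg,
            "speech_crop_s": self.speech_crop_s,
            "interruption_min_s": self.interruption_min_s,
            "min_track_points": self.min_track_points,
            "max_track_frames": self.max_track_frames,
            "kernel_width_deg": self.kernel_width_deg,
            "n_permutations": self.n_permutations,
        }
        for name, value in positive.items():
            if value <= 0:
                raise InvalidArgumentError(f"{name} must be > 0, got {value}")
        for name in ("scene_resolution_px", "scene_fov_deg",
                     "face_extent_deg", "template_px"):
            pair = getattr(self, name)
            setattr(self, name, tuple(pair))
            if len(pair) != 2 or any(v <= 0 for v in pair):
                raise InvalidArgumentError(
                    f"{name} must be a positive (x, y) pair, got {pair!r}")
        if not (0 < self.cluster_forming_p < 1 and 0 < self.cluster_alpha < 1):
            raise InvalidArgumentError("p thresholds must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise InvalidArgumentError("connectivity must be 4 or 8")
        if self.dispersion_metric not in ("max", "sum"):
            raise InvalidArgumentError("dispersion_metric must be 'max' or 'sum'")
        if self.transform_family not in ("similarity", "affine"):
            raise InvalidArgumentError(
                "transform_family must be 'similarity' or 'affine'")
        if self.deposit_mode not in ("fixation", "sample"):
            raise InvalidArgumentError("deposit_mode must be 'fixation' or 'sample'")
        ax_face = self.face_extent_deg[0] / self.face_extent_deg[1]
        ax_tmpl = self.template_px[0] / self.template_px[1]
        if abs(ax_face - ax_tmpl) > 1e-9:
            raise InvalidArgumentError(
                "template_px aspect ratio must match face_extent_deg "
                f"({ax_tmpl:.4f} vs {ax_face:.4f})")

    # ------------------------------------------------------------------
    # Derived scales
    @property
    def deg_per_px(self) -> tuple[float, float]:
        """Scene-camera degrees per pixel, per axis (small-angle linear)."""
        return (self.scene_fov_deg[0] / self.scene_resolution_px[0],
                self.scene_fov_deg[1] / self.scene_resolution_px[1])

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def template_deg_per_px(self) -> float:
        """Uniform template scale in degrees per template pixel."""
        return self.face_extent_deg[0] / self.template_px[0]

    def frame_of_time(self, t_ms) -> "int":
        """Scene-frame index containing gaze time ``t_ms``."""
        import numpy as np
        return np.floor(np.asarray(t_ms) * self.scene_fps / 1000.0).astype(int)

    # ------------------------------------------------------------------
    # Serialization (flat-key YAML)
    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key, value in data.items():
            if isinstance(value, tuple):
                data[key] = list(value)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(
                f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load a config from YAML, or return defaults when ``path`` is None."""
    if path is None:
        return AnalysisConfig()
    return AnalysisConfig.from_yaml(path)
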