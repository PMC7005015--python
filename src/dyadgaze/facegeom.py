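"""Face-box propagation and upper/lower/off-face gaze classification.

The face in each scene frame is a convex quadrilateral (vertices ordered
TL, TR, BR, BL). Between detections the box is propagated through point
correspondences tracked KLT-style on the face: a least-squares similarity
transform (translation + rotation + isotropic scale; optionally full
affine) is fitted to the correspondences and applied to the previous
box. Propagation is only trusted with at least ``min_track_points``
correspondences and for at most ``max_track_frames`` consecutive frames
from the last detection; otherwise a :class:`RedetectSignal` is returned
and the caller must supply a fresh detection.

Classification splits the quadrilateral at the midline joining the
midpoints of its left (TL-BL) and right (TR-BR) edges into an upper part
(proxy for the eye region) and a lower part (proxy for the mouth region).
Boundary conventions, fixed and documented: points exactly on a box edge
count as inside; points exactly on the midline are assigned to the upper
region.
"""

from __future__ import annotations

import enum
from dataclasses import InitVar, dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import InvalidArgumentError
from .fixation import Fixation

__all__ = ["FaceBox", "Region", "RedetectSignal", "fit_similarity",
           "fit_affine", "apply_transform", "propagate_box",
           "classify_point", "classify_fixation"]


class Region(enum.Enum):
    UPPER = "upper"
    LOWER = "lower"
    OUTSIDE = "outside"


@dataclass(frozen=True)
class RedetectSignal:
    """Propagation refused; a fresh face detection is required."""
    frame: int
    reason: str


def _cross(o, a, b):
    return ((a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1])
            - (a[..., 1] - o[..., 1]) * (b[..., 0] - o[..., 0]))


@dataclass(frozen=True)
class FaceBox:
    """Per-frame face quadrilateral, vertices ordered TL, TR, BR, BL.

    ``check=False`` skips convexity validation for trusted internal
    construction (e.g. boxes replayed from an already-validated track).
    """

    frame: int
    vertices: np.ndarray  # shape (4, 2), scene px
    source: str = "detected"  # "detected" | "propagated"
    check: InitVar[bool] = True

    def __post_init__(self, check: bool = True):
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if not check:
            return
        if v.shape != (4, 2):
            raise InvalidArgumentError("vertices must have shape (4, 2)")
        # convex + consistent winding: all consecutive edge crosses share
        # a strictly nonzero sign
        crosses = [_cross(v[i], v[(i + 1) % 4], v[(i + 2) % 4])
                   for i in range(4)]
        if min(crosses) * max(crosses) <= 0 or np.any(np.abs(crosses) < 1e-12):
            raise InvalidArgumentError(
                f"vertices of frame {self.frame} do not form a convex, "
                "non-degenerate quadrilateral")

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


# ----------------------------------------------------------------------
# Transform fitting

def fit_similarity(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares 2-D similarity transform (2x3 matrix) src -> dst.

    Solves for ``[[a, -b, tx], [b, a, ty]]`` minimising the summed squared
    residual over index-matched correspondences.
    """
    src = np.asarray(src, float); dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[0] < 2:
        raise InvalidArgumentError(
            "need >= 2 index-matched correspondences of equal shape")
    n = src.shape[0]
    x, y = src[:, 0], src[:, 1]
    u, v = dst[:, 0], dst[:, 1]
    sx, sy, su, sv = x.sum(), y.sum(), u.sum(), v.sum()
    d = n * (x @ x + y @ y) - sx * sx - sy * sy
    if abs(d) < 1e-12:
        raise InvalidArgumentError("correspondences are spatially degenerate")
    a = (n * (x @ u + y @ v) - sx * su - sy * sv) / d
    b = (n * (x @ v - y @ u) - sx * sv + sy * su) / d
    tx = (su - a * sx + b * sy) / n
    ty = (sv - b * sx - a * sy) / n
    return np.array([[a, -b, tx], [b, a, ty]])


def fit_affine(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares 2-D affine transform (2x3 matrix) src -> dst."""
    src = np.asarray(src, float); dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.shape[0] < 3:
        raise InvalidArgumentError("need >= 3 correspondences for affine")
    A = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
    return coef.T  # (2, 3)


def apply_transform(T: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.asarray(pts, float)
    return pts @ T[:, :2].T + T[:, 2]


# ----------------------------------------------------------------------
# Propagation

def propagate_box(points_prev: np.ndarray, points_curr: np.ndarray,
                  box_prev: FaceBox, frames_since_detection: int,
                  config: AnalysisConfig | None = None,
                  ) -> FaceBox | RedetectSignal:
    """Advance the face box by one frame through point correspondences.

    Returns the propagated :class:`FaceBox` when at least
    ``config.min_track_points`` correspondences are available and fewer
    than ``config.max_track_frames`` frames have elapsed since the last
    detection; otherwise a :class:`RedetectSignal`.
    """
    config = config or AnalysisConfig()
    points_prev = np.asarray(points_prev, float)
    points_curr = np.asarray(points_curr, float)
    if points_prev.shape != points_curr.shape:
        raise InvalidArgumentError("correspondence sets must be index-matched")
    n = len(points_prev)
    next_frame = box_prev.frame + 1
    if n < 3:
        raise InvalidArgumentError(
            f"{n} correspondences cannot constrain any transform")
    if frames_since_detection >= config.max_track_frames:
        return RedetectSignal(next_frame,
                              f"tracked {frames_since_detection} frames "
                              f">= limit {config.max_track_frames}")
    if n < config.min_track_points:
        return RedetectSignal(next_frame,
                              f"{n} points < minimum {config.min_track_points}")
    fit = fit_affine if config.transform_family == "affine" else fit_similarity
    T = fit(points_prev, points_curr)
    return FaceBox(frame=next_frame,
                   vertices=apply_transform(T, box_prev.vertices),
                   source="propagated")


# ----------------------------------------------------------------------
# Classification

def classify_point(p, box: FaceBox) -> Region:
    """Label a scene point as upper face, lower face, or outside.

    Inside test is edge-inclusive on the convex quadrilateral; the
    upper/lower split is the midline through the midpoints of the left
    and right edges, with on-midline points counted as upper.
    """
    p = np.asarray(p, float)
    v = box.vertices
    # edge-inclusive convex inside test against the box winding
    signs = [_cross(v[i], v[(i + 1) % 4], p) for i in range(4)]
    winding = _cross(v[0], v[1], v[2])
    if any(s * winding < 0 for s in signs):
        return Region.OUTSIDE
    left_mid = 0.5 * (v[0] + v[3])   # TL-BL
    right_mid = 0.5 * (v[1] + v[2])  # TR-BR
    side_p = _cross(left_mid, right_mid, p)
    side_top = _cross(left_mid, right_mid, v[0])  # TL defines "upper" side
    if side_p == 0 or side_p * side_top > 0:
        return Region.UPPER
    return Region.LOWER


def classify_fixation(f: Fixation, boxes: dict[int, FaceBox],
                      config: AnalysisConfig | None = None) -> Region | None:
    """Classify a fixation centroid against the face box of its frame.

    If no box exists for the fixation's frame, the nearest frame within
    ``config.box_gap_tolerance_frames`` is used (ties resolved toward the
    earlier frame); beyond the tolerance the fixation is unclassifiable
    and ``None`` is returned (treated as data loss downstream).
    """
    config = config or AnalysisConfig()
    box = boxes.get(f.frame)
    if box is None:
        for delta in range(1, config.box_gap_tolerance_frames + 1):
            box = boxes.get(f.frame - delta) or boxes.get(f.frame + delta)
            if box is not None:
                break
    if box is None:
        return None
    return classify_point(f.centroid, box)
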