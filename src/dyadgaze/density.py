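"""Normalized-face gaze density maps.

Because the face moves, scales and rotates with every scene frame,
face-directed gaze cannot be aggregated across time or participants in
scene coordinates. Each gaze point inside the face quadrilateral is
therefore re-mapped onto a fixed face template (110 x 140 px at
0.1 deg/px, i.e. the 11 x 14 degree face) by inverting the bilinear map
that carries the template corners onto the box vertices; for
parallelogram boxes this reduces to an affine (linear) transform.
Re-mapped fixations deposit their duration at their centroid pixel, maps
are smoothed with an isotropic Gaussian (2 degree width, interpreted as
sigma by default) whose truncated kernel is renormalized per source pixel
so that total mass is conserved at the template boundary, and finally
normalized to unit mass per participant so that participants with more
face time do not dominate group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .config import AnalysisConfig
from .errors import InsufficientDataError, InvalidArgumentError
from .facegeom import FaceBox, Region

__all__ = ["FaceTemplate", "DensityMap", "forward_map", "remap_to_template",
           "accumulate_density", "smooth_map", "pixelwise_t",
           "find_clusters", "Cluster"]


@dataclass(frozen=True)
class FaceTemplate:
    """Normalized face coordinate frame: TL corner at (0, 0)."""

    width_px: int = 110
    height_px: int = 140
    deg_per_px: float = 0.1

    @classmethod
    def from_config(cls, config: AnalysisConfig) -> "FaceTemplate":
        return cls(width_px=config.template_px[0],
                   height_px=config.template_px[1],
                   deg_per_px=config.template_deg_per_px)

    @property
    def extent_deg(self) -> tuple[float, float]:
        return (self.width_px * self.deg_per_px,
                self.height_px * self.deg_per_px)


@dataclass
class DensityMap:
    """Gaze density on the face template; ``values[y, x]`` row-major."""

    values: np.ndarray
    participant: str | None = None
    condition: str | None = None
    missing: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgumentError("density map must be 2-D")
        if np.any(self.values < 0):
            raise InvalidArgumentError("density values must be nonnegative")

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())


# ----------------------------------------------------------------------
# Quadrilateral <-> template mapping

def _corners(box: FaceBox):
    v = box.vertices
    tl, tr, br, bl = v[0], v[1], v[2], v[3]
    b1 = tr - tl
    b2 = bl - tl
    b3 = tl - tr + br - bl  # bilinear term; zero for parallelograms
    return tl, b1, b2, b3


def forward_map(template_pt, box: FaceBox,
                template: FaceTemplate | None = None) -> np.ndarray:
    """Map a template point (px) into scene coordinates via the bilinear
    map anchoring template corners to box vertices."""
    template = template or FaceTemplate()
    tp = np.asarray(template_pt, float)
    u = tp[..., 0] / template.width_px
    v = tp[..., 1] / template.height_px
    tl, b1, b2, b3 = _corners(box)
    return (tl + np.multiply.outer(u, b1) + np.multiply.outer(v, b2)
            + np.multiply.outer(u * v, b3))


def _cross2(a, b):
    return a[0] * b[1] - a[1] * b[0]


def remap_to_template(p, box: FaceBox,
                      template: FaceTemplate | None = None,
                      ) -> np.ndarray | None:
    """Map a scene point into template pixels; ``None`` if outside the box.

    The box corners TL, TR, BR, BL map exactly to the template corners
    (0, 0), (W, 0), (W, H), (0, H). Interior points are mapped by
    inverting the bilinear interpolation; for parallelogram boxes the
    quadratic degenerates and the map is affine.
    """
    template = template or FaceTemplate()
    p = np.asarray(p, float)
    from .facegeom import classify_point
    if classify_point(p, box) is Region.OUTSIDE:
        return None
    tl, b1, b2, b3 = _corners(box)
    q = p - tl
    # cross(b1 + v*b3, q - v*b2) = 0  =>  A v^2 + B v + C = 0
    A = _cross2(b2, b3)
    B = _cross2(b3, q) - _cross2(b1, b2)
    C = _cross2(b1, q)
    if abs(A) < 1e-12 * max(1.0, abs(B)):
        if abs(B) < 1e-15:
            raise InvalidArgumentError("degenerate box geometry")
        v = -C / B
    else:
        disc = B * B - 4 * A * C
        disc = max(disc, 0.0)
        r = math.sqrt(disc)
        roots = [(-B + r) / (2 * A), (-B - r) / (2 * A)]
        inside = [rv for rv in roots if -1e-9 <= rv <= 1 + 1e-9]
        v = inside[0] if inside else min(roots, key=lambda rv: abs(rv - 0.5))
    denom = b1 + v * b3
    if abs(denom[0]) >= abs(denom[1]):
        u = (q[0] - v * b2[0]) / denom[0]
    else:
        u = (q[1] - v * b2[1]) / denom[1]
    u = min(max(u, 0.0), 1.0)
    v = min(max(v, 0.0), 1.0)
    return np.array([u * template.width_px, v * template.height_px])


# ----------------------------------------------------------------------
# Density accumulation and smoothing

def accumulate_density(labeled_fixations: pd.DataFrame,
                       boxes: dict[int, FaceBox],
                       template: FaceTemplate | None = None,
                       participant: str | None = None,
                       condition: str | None = None) -> DensityMap:
    """Deposit on-face fixations onto the template grid.

    ``labeled_fixations`` needs columns ``x_px``, ``y_px`` (centroid),
    ``t_start_ms``, ``t_end_ms``, ``frame``, ``label``; only rows labeled
    upper/lower contribute, each depositing its duration (ms) at its
    remapped centroid pixel. A map with no on-face fixations is flagged
    missing.
    """
    template = template or FaceTemplate()
    grid = np.zeros((template.height_px, template.width_px))
    deposited = False
    on_face = labeled_fixations[
        labeled_fixations["label"].isin(["upper", "lower"])]
    for row in on_face.itertuples(index=False):
        box = boxes.get(int(row.frame))
        if box is None:
            continue
        tp = remap_to_template((row.x_px, row.y_px), box, template)
        if tp is None:
            continue
        ix = min(int(tp[0]), template.width_px - 1)
        iy = min(int(tp[1]), template.height_px - 1)
        grid[iy, ix] += row.t_end_ms - row.t_start_ms
        deposited = True
    return DensityMap(grid, participant=participant, condition=condition,
                      missing=not deposited)


def smooth_map(dmap: DensityMap, config: AnalysisConfig | None = None,
               template: FaceTemplate | None = None,
               normalize: bool = True) -> DensityMap:
    """Gaussian-smooth a density map; optionally normalize to unit mass.

    The kernel is isotropic with sigma = kernel width / template scale in
    pixels (or FWHM-derived when configured). At the template boundary
    the truncated kernel is renormalized per source pixel — dividing the
    input by the blurred all-ones mask before filtering — so that total
    mass is conserved exactly.
    """
    config = config or AnalysisConfig()
    template = template or FaceTemplate.from_config(config)
    width = config.kernel_width_deg
    if config.kernel_width_is_fwhm:
        width = width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    sigma = width / template.deg_per_px
    ones = np.ones_like(dmap.values)
    z = ndimage.gaussian_filter(ones, sigma=sigma, mode="constant")
    smoothed = ndimage.gaussian_filter(dmap.values / z, sigma=sigma,
                                       mode="constant")
    if normalize:
        mass = smoothed.sum()
        if mass > 0:
            smoothed = smoothed / mass
    return DensityMap(smoothed, participant=dmap.participant,
                      condition=dmap.condition, missing=dmap.missing)


# ----------------------------------------------------------------------
# Pixelwise statistics and clustering

def pixelwise_t(maps_a: list[DensityMap], maps_b: list[DensityMap],
                config: AnalysisConfig | None = None,
                ) -> tuple[np.ndarray, float, int]:
    """Two-sample pooled-variance t-map between two sets of maps.

    Missing maps are excluded. Pixels with zero pooled variance get t = 0
    when the group means agree and a +/-inf sentinel (always
    supra-threshold) otherwise. Returns (t_map, t_crit, df) where t_crit
    is the two-sided critical value at the cluster-forming p.
    """
    config = config or AnalysisConfig()
    a = np.stack([m.values for m in maps_a if not m.missing]) \
        if any(not m.missing for m in maps_a) else np.empty((0,))
    b = np.stack([m.values for m in maps_b if not m.missing]) \
        if any(not m.missing for m in maps_b) else np.empty((0,))
    if a.ndim != 3 or b.ndim != 3 or len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 non-missing maps per group")
    t_map = _t_from_stacks(a, b)
    df = len(a) + len(b) - 2
    t_crit = float(sps.t.ppf(1.0 - config.cluster_forming_p / 2.0, df))
    return t_map, t_crit, df


def _t_from_stacks(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    zero_var = denom == 0
    t[zero_var & (diff == 0)] = 0.0
    t[zero_var & (diff > 0)] = np.inf
    t[zero_var & (diff < 0)] = -np.inf
    return t


@dataclass
class Cluster:
    id: int
    sign: str            # "positive" | "negative"
    size: int            # pixel count
    pixels: np.ndarray   # (k, 2) array of (row, col) indices
    peak: tuple[int, int]  # (row, col) of max |t|
    p: float | None = None
    significant: bool = False


def _structure(connectivity: int) -> np.ndarray:
    return (np.ones((3, 3), bool) if connectivity == 8
            else ndimage.generate_binary_structure(2, 1))


def find_clusters(t_map: np.ndarray, t_crit: float,
                  connectivity: int = 8) -> list[Cluster]:
    """Connected supra-threshold clusters, signed.

    Positive clusters collect pixels with t > t_crit, negative clusters
    pixels with t < -t_crit, under the given pixel connectivity. Sizes
    are pixel counts (the cluster statistic).
    """
    structure = _structure(connectivity)
    clusters: list[Cluster] = []
    next_id = 1
    for sign, mask in (("positive", t_map > t_crit),
                       ("negative", t_map < -t_crit)):
        labels, n = ndimage.label(mask, structure=structure)
        for k in range(1, n + 1):
            pix = np.argwhere(labels == k)
            vals = np.abs(t_map[labels == k])
            peak = tuple(pix[int(np.argmax(vals))])
            clusters.append(Cluster(id=next_id, sign=sign, size=len(pix),
                                    pixels=pix, peak=peak))
            next_id += 1
    clusters.sort(key=lambda c: -c.size)
    return clusters
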