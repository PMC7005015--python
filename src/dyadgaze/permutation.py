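"""Cluster-based Monte Carlo permutation test on gaze density maps.

Pixelwise two-sample t statistics between two participant groups are
thresholded at the critical value for the cluster-forming p (0.01);
supra-threshold pixels are joined into signed connected clusters whose
statistic is their size in pixels. Under the null of exchangeable group
labels, participants' maps are randomly re-assigned to groups (preserving
group sizes); each iteration records the maximum cluster size over the
permuted map with positive and negative clusters pooled (|t|
thresholding). An observed cluster is significant when the proportion of
permutation maxima at least as large is below the family-wise alpha
(0.05); p-values use the (b + 1) / (m + 1) estimator so they can never be
exactly zero. An exhaustive mode enumerates every distinct group split
instead of sampling, for small designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import ndimage

from .config import AnalysisConfig
from .density import Cluster, DensityMap, _structure, _t_from_stacks, \
    find_clusters, pixelwise_t
from .errors import InsufficientDataError

__all__ = ["PermutationResult", "permutation_test"]


@dataclass
class PermutationResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    t_crit: float
    df: int
    null_max_sizes: np.ndarray
    n_iterations: int
    exhaustive: bool

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def significance_mask(self) -> np.ndarray:
        mask = np.zeros(self.t_map.shape, bool)
        for c in self.significant_clusters:
            mask[c.pixels[:, 0], c.pixels[:, 1]] = True
        return mask


def _max_cluster_sizes(t_maps: np.ndarray, t_crit: float,
                       structure: np.ndarray) -> np.ndarray:
    """Max pooled-sign supra-threshold cluster size per permuted t-map."""
    out = np.empty(len(t_maps), dtype=int)
    for i, tm in enumerate(t_maps):
        mask = np.abs(tm) > t_crit
        if not mask.any():
            out[i] = 0
            continue
        labels, n = ndimage.label(mask, structure=structure)
        out[i] = int(np.bincount(labels.ravel())[1:].max()) if n else 0
    return out


def permutation_test(maps: list[DensityMap], group_labels,
                     config: AnalysisConfig | None = None,
                     rng: np.random.Generator | int | None = None,
                     exhaustive: bool = False) -> PermutationResult:
    """Cluster-based permutation test of a two-group map difference.

    Parameters
    ----------
    maps, group_labels
        One smoothed, unit-mass density map per participant and the
        participant's group label (exactly two distinct labels).
    config
        Supplies cluster-forming p, iteration count, alpha, connectivity.
    rng
        Seed or generator for the Monte Carlo label shuffles (defaults to
        ``config.rng_seed``).
    exhaustive
        Enumerate all distinct group splits instead of Monte Carlo
        sampling (only sensible for small designs).
    """
    config = config or AnalysisConfig()
    if rng is None:
        rng = config.rng_seed
    rng = np.random.default_rng(rng)
    labels = np.asarray(group_labels)
    keep = np.array([not m.missing for m in maps])
    labels = labels[keep]
    maps = [m for m, k in zip(maps, keep) if k]
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise InsufficientDataError("exactly two group labels required")
    idx_a = np.flatnonzero(labels == uniq[0])
    idx_b = np.flatnonzero(labels == uniq[1])
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise InsufficientDataError("need >= 2 participants per group")

    maps_a = [maps[i] for i in idx_a]
    maps_b = [maps[i] for i in idx_b]
    t_map, t_crit, df = pixelwise_t(maps_a, maps_b, config)
    clusters = find_clusters(t_map, t_crit, config.connectivity)
    structure = _structure(config.connectivity)

    stack = np.stack([m.values for m in maps])
    n = len(stack)
    na = len(idx_a)
    flat = stack.reshape(n, -1)
    flat_sq = flat * flat
    shape = t_map.shape

    if exhaustive:
        choices = np.array(list(combinations(range(n), na)))
        n_iter = len(choices)
    else:
        n_iter = config.n_permutations
        choices = np.empty((n_iter, na), dtype=int)
        for i in range(n_iter):
            choices[i] = rng.permutation(n)[:na]

    null_max = np.empty(n_iter, dtype=int)
    chunk = max(1, min(256, n_iter))
    for lo in range(0, n_iter, chunk):
        sel = np.zeros((min(chunk, n_iter - lo), n), dtype=float)
        rows = choices[lo:lo + len(sel)]
        np.put_along_axis(sel, rows, 1.0, axis=1)
        nb = n - na
        sum_a = sel @ flat
        sum_a2 = sel @ flat_sq
        tot = flat.sum(axis=0)
        tot2 = flat_sq.sum(axis=0)
        ma = sum_a / na
        mb = (tot - sum_a) / nb
        ssa = sum_a2 - na * ma * ma
        ssb = (tot2 - sum_a2) - nb * mb * mb
        sp2 = np.maximum((ssa + ssb) / df, 0.0)  # guard fp cancellation
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        diff = ma - mb
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / denom
        zero = denom == 0
        t[zero & (diff == 0)] = 0.0
        t[zero & (diff > 0)] = np.inf
        t[zero & (diff < 0)] = -np.inf
        null_max[lo:lo + len(sel)] = _max_cluster_sizes(
            t.reshape(-1, *shape), t_crit, structure)

    for c in clusters:
        if exhaustive:
            c.p = float((null_max >= c.size).mean())
        else:
            c.p = float(((null_max >= c.size).sum() + 1) / (n_iter + 1))
        c.significant = c.p < config.cluster_alpha
    return PermutationResult(clusters=clusters, t_map=t_map, t_crit=t_crit,
                             df=df, null_max_sizes=null_max,
                             n_iterations=n_iter, exhaustive=exhaustive)
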