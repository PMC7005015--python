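"""Independent reference implementations used only to check the package.

Each oracle is written naively (exhaustive scans, flood fill, closed-form
sums of squares, full enumeration) and never shares code with the
implementation it verifies.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy import stats as sps


# ----------------------------------------------------------------------
# I-DT: windowed exhaustive scan, dispersion recomputed from scratch

def brute_force_idt(t, x, y, valid, min_dur_ms, max_disp_deg,
                    deg_per_px, metric="max"):
    """Greedy dispersion-threshold scan over each gap-free valid run."""
    t = np.asarray(t, float); x = np.asarray(x, float)
    y = np.asarray(y, float); valid = np.asarray(valid, bool)
    sx, sy = deg_per_px

    def disp(lo, hi):  # inclusive window
        xr = (x[lo:hi + 1].max() - x[lo:hi + 1].min()) * sx
        yr = (y[lo:hi + 1].max() - y[lo:hi + 1].min()) * sy
        return xr + yr if metric == "sum" else max(xr, yr)

    runs = []
    start = None
    for k in range(len(t)):
        if valid[k] and start is None:
            start = k
        elif not valid[k] and start is not None:
            runs.append((start, k - 1)); start = None
    if start is not None:
        runs.append((start, len(t) - 1))

    out = []
    eps = 1e-6  # same timing tolerance as the detector contract
    for lo, hi in runs:
        i = lo
        while i <= hi:
            j = i
            while j <= hi and t[j] - t[i] < min_dur_ms - eps:
                j += 1
            if j > hi:
                break
            if disp(i, j) > max_disp_deg:
                i += 1
                continue
            while j + 1 <= hi and disp(i, j + 1) <= max_disp_deg:
                j += 1
            out.append((float(t[i]), float(t[j])))
            i = j + 1
    return out


# ----------------------------------------------------------------------
# Point-in-quad region labels via shapely polygons

def shapely_region(p, vertices):
    """upper/lower/outside via explicit half-polygons (edge-inclusive;
    midline points resolve to upper)."""
    from shapely.geometry import Point, Polygon
    tl, tr, br, bl = [np.asarray(v, float) for v in vertices]
    lm = (tl + bl) / 2
    rm = (tr + br) / 2
    upper = Polygon([tl, tr, rm, lm])
    lower = Polygon([lm, rm, br, bl])
    pt = Point(*np.asarray(p, float))
    if upper.covers(pt):
        return "upper"
    if lower.covers(pt):
        return "lower"
    return "outside"


# ----------------------------------------------------------------------
# Connected components by breadth-first flood fill

def flood_fill_clusters(mask, connectivity=8):
    """List of sets of (row, col) per connected supra-threshold component."""
    mask = np.asarray(mask, bool)
    if connectivity == 8:
        nbrs = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for i, j in zip(*np.nonzero(mask)):
        if seen[i, j]:
            continue
        comp = set()
        q = deque([(i, j)])
        seen[i, j] = True
        while q:
            a, b = q.popleft()
            comp.add((a, b))
            for di, dj in nbrs:
                u, v = a + di, b + dj
                if (0 <= u < mask.shape[0] and 0 <= v < mask.shape[1]
                        and mask[u, v] and not seen[u, v]):
                    seen[u, v] = True
                    q.append((u, v))
        comps.append(comp)
    return comps


# ----------------------------------------------------------------------
# Classical cell-means split-plot sums of squares (balanced designs)

def split_plot_anova_ss(y):
    """F and partial eta^2 from the classical SS decomposition.

    ``y`` has shape (group, subject, speech, task), balanced.
    Returns {effect: (F, partial_eta_sq)}.
    """
    y = np.asarray(y, float)
    a, n, b, c = y.shape
    grand = y.mean()
    m_g = y.mean(axis=(1, 2, 3))
    m_gi = y.mean(axis=(2, 3))
    m_s = y.mean(axis=(0, 1, 3))
    m_t = y.mean(axis=(0, 1, 2))
    m_gs = y.mean(axis=(1, 3))
    m_gt = y.mean(axis=(1, 2))
    m_st = y.mean(axis=(0, 1))
    m_gis = y.mean(axis=3)
    m_git = y.mean(axis=2)
    m_gst = y.mean(axis=1)

    ss_group = n * b * c * ((m_g - grand) ** 2).sum()
    ss_subj = b * c * ((m_gi - m_g[:, None]) ** 2).sum()
    ss_speech = a * n * c * ((m_s - grand) ** 2).sum()
    ss_sg = n * c * ((m_gs - m_g[:, None] - m_s[None, :] + grand) ** 2).sum()
    ss_s_err = c * ((m_gis - m_gi[:, :, None] - m_gs[:, None, :]
                     + m_g[:, None, None]) ** 2).sum()
    ss_task = a * n * b * ((m_t - grand) ** 2).sum()
    ss_tg = n * b * ((m_gt - m_g[:, None] - m_t[None, :] + grand) ** 2).sum()
    ss_t_err = b * ((m_git - m_gi[:, :, None] - m_gt[:, None, :]
                     + m_g[:, None, None]) ** 2).sum()
    ss_st = a * n * ((m_st - m_s[:, None] - m_t[None, :] + grand) ** 2).sum()
    ss_stg = n * ((m_gst - m_gs[:, :, None] - m_gt[:, None, :]
                   - m_st[None, :, :] + m_g[:, None, None]
                   + m_s[None, :, None] + m_t[None, None, :]
                   - grand) ** 2).sum()
    resid = (y - m_gis[:, :, :, None] - m_git[:, :, None, :]
             + m_gi[:, :, None, None]
             - m_gst[:, None, :, :] + m_gs[:, None, :, None]
             + m_gt[:, None, None, :] - m_g[:, None, None, None])
    ss_st_err = (resid ** 2).sum()

    df_err = a * (n - 1)
    out = {}
    for name, ss, ss_err in (
            ("Group", ss_group, ss_subj),
            ("Speech", ss_speech, ss_s_err),
            ("Speech x Group", ss_sg, ss_s_err),
            ("Task", ss_task, ss_t_err),
            ("Task x Group", ss_tg, ss_t_err),
            ("Speech x Task", ss_st, ss_st_err),
            ("Speech x Task x Group", ss_stg, ss_st_err)):
        f = (ss / 1.0) / (ss_err / df_err)
        out[name] = (f, ss / (ss + ss_err))
    return out


# ----------------------------------------------------------------------
# Exhaustive cluster-permutation reference

def exhaustive_cluster_p(values, n_a, t_crit, connectivity=8):
    """Cluster p-values by enumerating every split of the stacked maps.

    ``values``: (n, H, W) array; first ``n_a`` rows are group A in the
    observed labeling. Observed clusters are |t|-thresholded signed
    components; each p is the fraction of all C(n, n_a) relabelings whose
    maximum pooled cluster size reaches the observed size.
    """
    values = np.asarray(values, float)
    n = len(values)

    def tmap(idx_a):
        idx_a = list(idx_a)
        idx_b = [k for k in range(n) if k not in idx_a]
        res = sps.ttest_ind(values[idx_a], values[idx_b], axis=0)
        t = np.nan_to_num(res.statistic, nan=0.0)
        return t

    obs = tmap(range(n_a))
    obs_sizes = [len(c) for sign in (1, -1)
                 for c in flood_fill_clusters(sign * obs > t_crit,
                                              connectivity)]
    maxima = []
    for idx_a in itertools.combinations(range(n), n_a):
        t = tmap(idx_a)
        comps = flood_fill_clusters(np.abs(t) > t_crit, connectivity)
        maxima.append(max((len(c) for c in comps), default=0))
    maxima = np.asarray(maxima)
    return obs_sizes, [float((maxima >= s).mean()) for s in obs_sizes]


# ----------------------------------------------------------------------
# Exact Spearman p by full rank-permutation enumeration

def spearman_exact(x, y):
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        hits += abs(r) >= obs - 1e-12
        total += 1
    return float(np.corrcoef(rx, ry)[0, 1]), hits / total
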