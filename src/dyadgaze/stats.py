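"""Statistical battery for the ROI analysis.

* 2 (Group, between) x 2 (Speech, within) x 2 (Task, within) mixed
  split-plot ANOVA with partial eta-squared effect sizes. With only
  two levels per within factor, sphericity holds trivially and no
  correction is applied. The ANOVA is computed from per-subject contrast
  scores stratum by stratum (between; Speech; Task; Speech x Task), which
  in the balanced case is algebraically identical to the classical
  cell-means sums-of-squares decomposition and generalises to unequal
  group sizes as Type-III tests.
* Nonparametric follow-ups: Wilcoxon signed-rank (within), Mann-Whitney U
  (between), each with the r = Z / sqrt(N) effect-size convention
  (N = number of observations entering the test), plus a Shapiro-Wilk
  normality screen.
* Trait analysis: Spearman correlations (exact small-sample p by full
  rank-permutation enumeration when feasible) and two-sample t tests on
  trait scores with Cohen's d (pooled SD).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError

__all__ = ["mixed_anova_2x2x2", "wilcoxon_signed_rank", "mann_whitney_u",
           "shapiro_screen", "spearman", "cohens_d_ttest", "trait_analysis",
           "median_iqr_table"]


# ----------------------------------------------------------------------
# Mixed 2x2x2 ANOVA

def _stratum_tests(d: np.ndarray, g: np.ndarray):
    """Type-III main-effect and group-interaction F from contrast scores.

    ``d`` holds one within-subject contrast per subject, ``g`` the group
    label. Returns ((SS_main, F_main), (SS_inter, F_inter), SS_err, df_err).
    """
    groups = np.unique(g)
    means = np.array([d[g == k].mean() for k in groups])
    ns = np.array([(g == k).sum() for k in groups])
    ss_err = float(sum(((d[g == k] - d[g == k].mean()) ** 2).sum()
                       for k in groups))
    df_err = len(d) - len(groups)
    inv = (1.0 / ns).sum()
    # main effect: unweighted mean of group means vs 0
    est = means.mean()
    ss_main = est ** 2 / (inv / 4.0)
    # interaction with Group: difference of group means
    ss_inter = (means[0] - means[1]) ** 2 / inv
    ms_err = ss_err / df_err
    return (ss_main, ss_main / ms_err), (ss_inter, ss_inter / ms_err), \
        ss_err, df_err


def mixed_anova_2x2x2(outcomes: pd.DataFrame, dependent: str,
                      group_of: pd.Series | dict | None = None,
                      ) -> pd.DataFrame:
    """Split-plot ANOVA: Group (between) x Speech x Task (within).

    ``outcomes`` is long-format with columns ``participant``, ``task``,
    ``speech_state``, the dependent column, and either a ``group`` column
    or a separate ``group_of`` mapping. Participants without all four
    complete within-subject cells are dropped listwise.

    Returns a tidy table with one row per effect: F, df1, df2, p,
    partial eta squared.
    """
    df = outcomes.copy()
    if group_of is not None:
        df["group"] = df["participant"].map(group_of)
    if "group" not in df:
        raise InsufficientDataError("no group assignment provided")
    df = df.dropna(subset=[dependent])
    wide = df.pivot_table(index=["participant", "group"],
                          columns=["speech_state", "task"],
                          values=dependent, aggfunc="mean")
    wide = wide.dropna()
    if wide.shape[1] != 4:
        raise InsufficientDataError(
            "need 2 speech states x 2 tasks of data")
    groups = wide.index.get_level_values("group").to_numpy()
    uniq = np.unique(groups)
    if len(uniq) != 2 or min((groups == k).sum() for k in uniq) < 2:
        raise InsufficientDataError(
            "need two groups with >= 2 complete participants each")

    states = sorted({c[0] for c in wide.columns})
    tasks = sorted({c[1] for c in wide.columns})
    y = np.stack([[wide[(s, t)].to_numpy() for t in tasks] for s in states])
    # y has shape (speech, task, subject)
    subj_mean = y.mean(axis=(0, 1))
    c_speech = y[1].mean(axis=0) - y[0].mean(axis=0)
    c_task = y[:, 1].mean(axis=0) - y[:, 0].mean(axis=0)
    c_inter = y[1, 1] - y[1, 0] - y[0, 1] + y[0, 0]

    rows = []

    def add(effect, ss, f, ss_err, df_err):
        p = sps.f.sf(f, 1, df_err)
        rows.append({"effect": effect, "F": f, "df1": 1, "df2": df_err,
                     "p": p, "partial_eta_sq": ss / (ss + ss_err)})

    # between stratum: one-way on subject means (scaled by the 4 within
    # observations so SS match the classical table in the balanced case)
    m = subj_mean * 2.0  # sqrt(4): SS scale only; F and eta are invariant
    g_means = np.array([m[groups == k].mean() for k in uniq])
    ns = np.array([(groups == k).sum() for k in uniq])
    ss_g = (g_means[0] - g_means[1]) ** 2 / (1.0 / ns).sum()
    ss_err_b = float(sum(((m[groups == k] - m[groups == k].mean()) ** 2).sum()
                         for k in uniq))
    df_err = len(m) - 2
    add("Group", ss_g, ss_g / (ss_err_b / df_err), ss_err_b, df_err)

    (ss_s, f_s), (ss_sg, f_sg), ss_e, dfe = _stratum_tests(c_speech, groups)
    add("Speech", ss_s, f_s, ss_e, dfe)
    add("Speech x Group", ss_sg, f_sg, ss_e, dfe)
    (ss_t, f_t), (ss_tg, f_tg), ss_e, dfe = _stratum_tests(c_task, groups)
    add("Task", ss_t, f_t, ss_e, dfe)
    add("Task x Group", ss_tg, f_tg, ss_e, dfe)
    (ss_st, f_st), (ss_stg, f_stg), ss_e, dfe = _stratum_tests(
        c_inter / 2.0, groups)  # scale irrelevant to F / eta
    add("Speech x Task", ss_st, f_st, ss_e, dfe)
    add("Speech x Task x Group", ss_stg, f_stg, ss_e, dfe)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Nonparametric follow-ups

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    z: float
    r: float
    method: str


def wilcoxon_signed_rank(x, y=None) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on pairs (or differences).

    Exact p via scipy's enumeration when there are no ties or zeros and
    n <= 25, else the normal approximation with tie correction. The
    effect size is r = Z / sqrt(N) with N = 2 x number of pairs (two
    observations per pair enter the test).
    """
    d = np.asarray(x, float) - (np.asarray(y, float) if y is not None else 0.0)
    d = d[~np.isnan(d)]
    if len(d) == 0 or np.all(d == 0):
        raise DegenerateDataError("all paired differences are zero")
    nz = d[d != 0]
    n = len(nz)
    ranks = sps.rankdata(np.abs(nz))
    w_plus = ranks[nz > 0].sum()
    mu = n * (n + 1) / 4.0
    # tie correction for the variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - (counts ** 3 - counts).sum() / 48.0
    z = (w_plus - mu) / math.sqrt(sigma2)
    has_ties = np.any(counts > 1)
    if n <= 25 and not has_ties:
        p = float(sps.wilcoxon(nz, method="exact").pvalue)
        method = "exact"
    else:
        p = 2.0 * sps.norm.sf(abs(z))
        method = "normal-approx"
    return TestResult(float(w_plus), p, float(z),
                      float(z / math.sqrt(2 * len(d))), method)


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U; r = Z / sqrt(n1 + n2)."""
    a = np.asarray(a, float); a = a[~np.isnan(a)]
    b = np.asarray(b, float); b = b[~np.isnan(b)]
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    nt = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (nt * (nt - 1))
    sigma2 = n1 * n2 / 12.0 * (nt + 1 - tie_term)
    z = (u1 - mu) / math.sqrt(sigma2) if sigma2 > 0 else 0.0
    has_ties = np.any(counts > 1)
    if max(n1, n2) <= 10 and not has_ties:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue)
        method = "exact"
    else:
        p = 2.0 * sps.norm.sf(abs(z)) if sigma2 > 0 else 1.0
        method = "normal-approx"
    return TestResult(float(u1), p, float(z), float(z / math.sqrt(nt)), method)


def shapiro_screen(values) -> tuple[float, float]:
    """Shapiro-Wilk normality screen; returns (W, p)."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if len(v) < 3:
        raise InsufficientDataError("Shapiro-Wilk needs >= 3 observations")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------------
# Correlations and trait comparisons

def spearman(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p.

    For n <= ``exact_max_n`` with untied data the p-value is exact,
    computed by enumerating all rank permutations; otherwise the t
    approximation is used.
    """
    x = np.asarray(x, float); y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise InsufficientDataError("need >= 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("constant vector: correlation undefined")
    rho = float(sps.spearmanr(x, y).correlation)
    ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if n <= exact_max_n and not ties:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        observed = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= observed - 1e-12
            total += 1
        return rho, count / total
    return rho, float(sps.spearmanr(x, y).pvalue)


def cohens_d_ttest(a, b, pooled: bool = True) -> dict:
    """Two-sample t test (pooled by default) with Cohen's d."""
    a = np.asarray(a, float); a = a[~np.isnan(a)]
    b = np.asarray(b, float); b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    s_pool = math.sqrt(((len(a) - 1) * a.var(ddof=1)
                        + (len(b) - 1) * b.var(ddof=1))
                       / (len(a) + len(b) - 2))
    d = (a.mean() - b.mean()) / s_pool if s_pool > 0 else np.nan
    df = len(a) + len(b) - 2 if pooled else float(res.df)
    return {"t": float(res.statistic), "df": df, "p": float(res.pvalue),
            "d": float(d), "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
            "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1))}


def trait_analysis(outcomes: pd.DataFrame, traits: pd.DataFrame,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlations of trait scores with gaze metrics, per group,
    plus between-group t tests on each trait.

    ``outcomes`` as from :func:`dyadgaze.roi.compute_proportions` (long);
    ``traits`` with columns ``participant``, ``group``, ``aq``, ``lsas``.

    Face looking is correlated separately per task (task effects exist);
    upper-face looking is collapsed across tasks (no task effect), each
    split by speech state — mirroring the layout of the trait-correlation
    table of the ROI analysis.
    """
    metrics = {}
    for state in sorted(outcomes["speech_state"].unique()):
        sub = outcomes[outcomes["speech_state"] == state]
        for task in sorted(sub["task"].unique()):
            cell = sub[sub["task"] == task]
            metrics[f"face_{task}_{state}"] = cell.set_index(
                "participant")["face_prop"]
        metrics[f"upper_{state}"] = sub.groupby(
            "participant")["upper_prop"].mean()

    tr = traits.set_index("participant")
    corr_rows = []
    for grp in sorted(tr["group"].unique()):
        members = tr.index[tr["group"] == grp]
        for trait in ("aq", "lsas"):
            for name, series in metrics.items():
                common = members.intersection(series.index)
                x = tr.loc[common, trait].to_numpy(float)
                y = series.loc[common].to_numpy(float)
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 4:
                    continue
                rho, p = spearman(x[ok], y[ok])
                corr_rows.append({"group": grp, "trait": trait,
                                  "metric": name, "n": int(ok.sum()),
                                  "rho": rho, "p": p})
    groups = sorted(tr["group"].unique())
    ttest_rows = []
    if len(groups) == 2:
        for trait in ("aq", "lsas"):
            res = cohens_d_ttest(tr.loc[tr["group"] == groups[0], trait],
                                 tr.loc[tr["group"] == groups[1], trait])
            ttest_rows.append({"trait": trait, "group_a": groups[0],
                               "group_b": groups[1], **res})
    return pd.DataFrame(corr_rows), pd.DataFrame(ttest_rows)


def median_iqr_table(outcomes: pd.DataFrame, dependent: str,
                     group_of: pd.Series | dict | None = None) -> pd.DataFrame:
    """Medians and interquartile ranges (in %) per group x task x speech
    state — the descriptive layout of the ROI summary tables."""
    df = outcomes.copy()
    if group_of is not None:
        df["group"] = df["participant"].map(group_of)
    rows = []
    for (grp, task, state), cell in df.groupby(["group", "task",
                                                "speech_state"]):
        v = cell[dependent].dropna().to_numpy(float) * 100.0
        if len(v) == 0:
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"group": grp, "task": task, "speech_state": state,
                     "median_pct": med, "iqr_pct": q3 - q1, "n": len(v)})
    return pd.DataFrame(rows)
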