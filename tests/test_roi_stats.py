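"""ROI proportions and the statistical battery against hand oracles."""

import numpy as np
import pandas as pd
import pytest

from dyadgaze import (DegenerateDataError, InsufficientDataError,
                      cohens_d_ttest, compute_proportions, mann_whitney_u,
                      median_iqr_table, mixed_anova_2x2x2, shapiro_screen,
                      spearman, trait_analysis, wilcoxon_signed_rank)
from dyadgaze.speech import SpeechPeriod

from oracles import spearman_exact, split_plot_anova_ss


def fixation_rows(rows, participant="P1", task="introduction"):
    return pd.DataFrame([
        {"participant": participant, "task": task, "t_start_ms": float(t0),
         "t_end_ms": float(t1), "label": lab} for t0, t1, lab in rows])


PERIOD = [SpeechPeriod("P1", "introduction", "speaking", 0.0, 10_000.0, 1)]


class TestProportions:
    def test_hand_built_toy_cell(self):
        # within one 10 s period: 2 s upper + 1 s lower + 1 s outside
        # fixation time (plus loss elsewhere); proportions use valid
        # fixation time only
        fx = fixation_rows([(0, 2000, "upper"), (3000, 4000, "lower"),
                            (5000, 6000, "outside")])
        out = compute_proportions(fx, PERIOD)
        row = out.iloc[0]
        assert row.face_prop == pytest.approx(3000 / 4000)
        assert row.upper_prop == pytest.approx(2000 / 3000)
        assert row.period_ms == pytest.approx(10_000)

    def test_fixation_clipped_at_period_boundary(self):
        # 4 s fixation straddling the period end contributes only 2 s
        fx = fixation_rows([(8000, 12_000, "upper")])
        row = compute_proportions(fx, PERIOD).iloc[0]
        assert row.upper_ms == pytest.approx(2000)
        assert row.face_prop == 1.0

    def test_all_upper_gives_unit_proportions(self):
        fx = fixation_rows([(0, 1000, "upper"), (2000, 3000, "upper")])
        row = compute_proportions(fx, PERIOD).iloc[0]
        assert row.face_prop == 1.0 and row.upper_prop == 1.0

    def test_no_face_fixations_upper_prop_missing(self):
        fx = fixation_rows([(0, 1000, "outside")])
        row = compute_proportions(fx, PERIOD).iloc[0]
        assert row.face_prop == 0.0
        assert np.isnan(row.upper_prop)

    def test_empty_cell_flagged_missing(self):
        fx = fixation_rows([(0, 1000, "unclassifiable")])
        row = compute_proportions(fx, PERIOD).iloc[0]
        assert row.missing
        assert np.isnan(row.face_prop)

    def test_loss_fraction_from_gaze_validity(self):
        fx = fixation_rows([(0, 2000, "upper")])
        dt = 1000.0 / 60.0
        n = 600  # 10 s
        gaze = pd.DataFrame({
            "participant": "P1", "task": "introduction",
            "t_ms": np.arange(n) * dt,
            "valid": np.repeat([True, False, True], [300, 60, 240])})
        row = compute_proportions(fx, PERIOD, gaze).iloc[0]
        assert row.valid_ms == pytest.approx(540 * dt)
        assert row.loss_frac == pytest.approx(1 - 540 * dt / 10_000)


def make_outcomes(y, groups):
    """Long-format outcomes from y[group, subject, speech, task]."""
    rows = []
    for g in range(y.shape[0]):
        for i in range(y.shape[1]):
            pid = f"{groups[g]}{i}"
            for s, state in enumerate(["speaking", "listening"]):
                for t, task in enumerate(["introduction", "storytelling"]):
                    rows.append({"participant": pid, "group": groups[g],
                                 "task": task, "speech_state": state,
                                 "value": y[g, i, s, t]})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_hand_sums_of_squares(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(2, 3, 2, 2))  # 2 groups x 3 subjects x 2 x 2
        out = mixed_anova_2x2x2(make_outcomes(y, "AB"), "value")
        expected = split_plot_anova_ss(y)
        for row in out.itertuples(index=False):
            f_exp, eta_exp = expected[row.effect]
            assert row.F == pytest.approx(f_exp, rel=1e-10), row.effect
            assert row.partial_eta_sq == pytest.approx(eta_exp, rel=1e-10)
            assert row.df1 == 1 and row.df2 == 4

    def test_location_invariance(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(2, 5, 2, 2))
        base = mixed_anova_2x2x2(make_outcomes(y, "AB"), "value")
        shifted = mixed_anova_2x2x2(make_outcomes(y + 17.3, "AB"), "value")
        np.testing.assert_allclose(base["F"], shifted["F"], rtol=1e-9)

    def test_null_p_values_roughly_uniform(self):
        """Under pure noise the p-value of each effect should be
        uniform; checked with a KS test over simulation replicates."""
        from scipy import stats as sps
        rng = np.random.default_rng(7)
        pvals = {e: [] for e in ["Group", "Speech", "Task"]}
        for _ in range(200):
            y = rng.normal(size=(2, 10, 2, 2))
            out = mixed_anova_2x2x2(make_outcomes(y, "AB"), "value")
            for e in pvals:
                pvals[e].append(
                    float(out.loc[out["effect"] == e, "p"].iloc[0]))
        for e, ps in pvals.items():
            assert sps.kstest(ps, "uniform").pvalue > 0.01, e

    def test_insufficient_groups_rejected(self):
        y = np.random.default_rng(8).normal(size=(2, 3, 2, 2))
        df = make_outcomes(y, "AB")
        with pytest.raises(InsufficientDataError):
            mixed_anova_2x2x2(df[df["group"] == "A"], "value")

    def test_incomplete_participants_dropped_listwise(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(2, 4, 2, 2))
        df = make_outcomes(y, "AB")
        # knock out one cell of A0 and of B0 -> those subjects must not
        # count, leaving a balanced 3-per-group design
        df.loc[df["participant"].isin(["A0", "B0"])
               & (df["speech_state"] == "speaking")
               & (df["task"] == "introduction"), "value"] = np.nan
        out = mixed_anova_2x2x2(df, "value")
        expected = split_plot_anova_ss(y[:, 1:])
        for row in out.itertuples(index=False):
            assert row.F == pytest.approx(expected[row.effect][0], rel=1e-10)


class TestNonparametric:
    def test_wilcoxon_exact_enumeration_example(self):
        # pairs (1,2),(2,4),(3,6): all differences positive; only the
        # 2/8 extreme sign assignments are as large -> p = 0.25
        res = wilcoxon_signed_rank([2, 4, 6], [1, 2, 3])
        assert res.p == pytest.approx(0.25)
        assert res.method == "exact"

    def test_wilcoxon_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_mann_whitney_exact_enumeration_example(self):
        # {1,2,3} vs {4,5,6}: U = 0; 2 of C(6,3)=20 splits as extreme
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)

    def test_identical_samples_no_effect(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p == pytest.approx(1.0, abs=0.05)
        assert abs(res.r) < 1e-9

    def test_effect_size_convention_z_over_sqrt_n(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 26)
        res = mann_whitney_u(a, b)
        assert res.r == pytest.approx(res.z / np.sqrt(56))
        resw = wilcoxon_signed_rank(a[:25], b[:25])
        assert resw.r == pytest.approx(resw.z / np.sqrt(50))

    def test_shapiro_screen_flags_skew(self):
        rng = np.random.default_rng(11)
        _, p_normal = shapiro_screen(rng.normal(size=200))
        _, p_skewed = shapiro_screen(rng.exponential(size=200) ** 2)
        assert p_normal > 0.01 and p_skewed < 1e-6


class TestSpearmanAndTraits:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        rho, _ = spearman(x, [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, [50, 40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_full_enumeration_at_n5(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        rho, p = spearman(x, y)
        rho_exp, p_exp = spearman_exact(x, y)
        assert rho == pytest.approx(rho_exp)
        assert p == pytest.approx(p_exp)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_pooled_t_and_cohens_d(self):
        a = [14.0, 10.0, 18.0, 12.0]
        b = [22.0, 26.0, 20.0, 24.0]
        res = cohens_d_ttest(a, b)
        # hand computation: means 13.5 vs 23, pooled sd sqrt(
        # (3*11.667+3*6.667)/6) = 3.0276...
        assert res["df"] == 6
        assert res["d"] == pytest.approx((13.5 - 23.0) / 3.02765, rel=1e-4)
        assert res["p"] < 0.01

    def test_trait_analysis_recovers_injected_correlation(self):
        rng = np.random.default_rng(13)
        participants = [f"A{i}" for i in range(20)]
        upper = rng.uniform(0.2, 0.9, 20)
        aq = 30 - 20 * upper + rng.normal(0, 1.0, 20)  # strongly negative
        rows = []
        for pid, u in zip(participants, upper):
            for state in ("speaking", "listening"):
                for task in ("introduction", "storytelling"):
                    rows.append({"participant": pid, "task": task,
                                 "speech_state": state,
                                 "face_prop": u, "upper_prop": u})
        outcomes = pd.DataFrame(rows)
        traits = pd.DataFrame({"participant": participants, "group": "A",
                               "aq": aq, "lsas": rng.normal(40, 10, 20)})
        corr, ttests = trait_analysis(outcomes, traits)
        sub = corr[(corr["trait"] == "aq")
                   & (corr["metric"] == "upper_speaking")]
        assert sub["rho"].iloc[0] < -0.8
        assert sub["p"].iloc[0] < 0.001
        assert ttests.empty  # single group: no between-group t test

    def test_median_iqr_layout(self):
        y = np.random.default_rng(14).uniform(0, 1, size=(2, 6, 2, 2))
        df = make_outcomes(y, "AB").rename(columns={"value": "face_prop"})
        table = median_iqr_table(df, "face_prop",
                                 {f"{g}{i}": g for g in "AB"
                                  for i in range(6)})
        assert len(table) == 8  # 2 groups x 2 tasks x 2 states
        assert ((table["median_pct"] >= 0) & (table["median_pct"] <= 100)).all()
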