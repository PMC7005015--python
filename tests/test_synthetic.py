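"""Contracts of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dyadgaze import (AnalysisConfig, InvalidArgumentError,
                      detect_fixations)
from dyadgaze.facegeom import apply_transform
from dyadgaze.synthetic import (CohortSpec, GazeProfile, InjectedEffect,
                                default_profiles, generate_cohort,
                                generate_face_track, generate_session,
                                make_speech_schedule,
                                sample_template_points, with_off_face)


class TestFaceTrack:
    def test_zero_motion_gives_identical_frames(self):
        track = generate_face_track(50, motion_amplitude_px=0.0, seed=1)
        first = track.boxes[0].vertices
        for box in track.boxes[1:]:
            np.testing.assert_array_equal(box.vertices, first)

    def test_dropout_schedule_controls_point_counts(self):
        schedule = np.full(20, 30)
        schedule[7] = 10  # forces re-detection downstream at frame 7
        track = generate_face_track(20, 30.0, dropout_schedule=schedule,
                                    seed=2)
        assert len(track.points[7]) == 10
        assert all(len(track.points[k]) == 30 for k in range(20) if k != 7)

    def test_correspondences_are_exact_transform_images(self):
        track = generate_face_track(60, 50.0, seed=3)
        for k in range(60):
            expected = apply_transform(track.transforms[k], track.anchors)
            np.testing.assert_array_equal(track.points[k],
                                          expected[:len(track.points[k])])

    def test_boxes_stay_inside_scene(self):
        cfg = AnalysisConfig()
        track = generate_face_track(200, 80.0, seed=4, config=cfg)
        for box in track.boxes:
            assert np.all(box.vertices >= 0)
            assert np.all(box.vertices[:, 0] <= cfg.scene_resolution_px[0])
            assert np.all(box.vertices[:, 1] <= cfg.scene_resolution_px[1])

    def test_seed_determinism(self):
        a = generate_face_track(40, 25.0, seed=9)
        b = generate_face_track(40, 25.0, seed=9)
        for ba, bb in zip(a.boxes, b.boxes):
            np.testing.assert_array_equal(ba.vertices, bb.vertices)

    def test_invalid_frame_count_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_face_track(0, 10.0)


class TestSession:
    def test_exact_60hz_spacing(self):
        track = generate_face_track(48, 0.0, seed=5)
        gaze, _ = generate_session(track, default_profiles()["western"],
                                   seed=6)
        dt = np.diff(gaze["t_ms"].to_numpy())
        np.testing.assert_allclose(dt, 1000.0 / 60.0, rtol=1e-12)

    def test_zero_loss_all_valid(self):
        track = generate_face_track(48, 0.0, seed=7)
        gaze, _ = generate_session(track, default_profiles()["western"],
                                   loss_rate=0.0, seed=8)
        assert gaze["valid"].all()

    def test_loss_rate_approximately_met(self):
        track = generate_face_track(2400, 0.0, seed=9)  # 100 s
        gaze, _ = generate_session(track, default_profiles()["western"],
                                   loss_rate=0.15, seed=10)
        frac = 1.0 - gaze["valid"].mean()
        # binomial-ish error, inflated by run-length correlation
        assert frac == pytest.approx(0.15, abs=0.04)

    def test_loss_comes_in_contiguous_runs(self):
        track = generate_face_track(2400, 0.0, seed=11)
        gaze, _ = generate_session(track, default_profiles()["western"],
                                   loss_rate=0.15, seed=12)
        invalid = (~gaze["valid"].to_numpy()).astype(int)
        switches = np.abs(np.diff(invalid)).sum()
        runs = max(1, (switches + invalid[0] + invalid[-1]) // 2)
        mean_run = invalid.sum() / runs
        assert mean_run > 3.0  # geometric runs, not i.i.d. drops

    def test_seed_determinism(self):
        track = generate_face_track(48, 20.0, seed=13)
        g1, _ = generate_session(track, default_profiles()["eastern"],
                                 loss_rate=0.1, seed=14)
        g2, _ = generate_session(track, default_profiles()["eastern"],
                                 loss_rate=0.1, seed=14)
        pd.testing.assert_frame_equal(g1, g2)

    def test_single_upper_component_classifies_upper(self):
        """A profile concentrated at the upper-face centroid with no
        off-face weight yields >= 99% upper-classified fixations."""
        from dyadgaze import classify_fixation
        profile = GazeProfile(components=(((5.5, 3.5), 0.6, 1.0),))
        track = generate_face_track(720, 15.0, seed=15)
        gaze, _ = generate_session(track, profile, seed=16)
        fixations, _ = detect_fixations(gaze)
        boxes = track.boxes_by_frame()
        labels = [classify_fixation(f, boxes) for f in fixations]
        assert len(labels) > 50
        upper = sum(lab is not None and lab.value == "upper"
                    for lab in labels)
        assert upper / len(labels) >= 0.99

    def test_empty_track_rejected(self):
        track = generate_face_track(5, 0.0, seed=17)
        track.boxes = []
        with pytest.raises(InvalidArgumentError):
            generate_session(track, default_profiles()["western"])


class TestCohort:
    def test_design_counts(self):
        spec = CohortSpec(n_per_group=2, session_duration_s=5.0, seed=18)
        cohort = generate_cohort(spec, default_profiles()["western"],
                                 default_profiles()["eastern"])
        assert len(cohort.participants) == 4
        cells = cohort.gaze.groupby(["participant", "task"]).size()
        assert len(cells) == 4 * 2  # participants x tasks
        assert set(cohort.traits["group"]) == {"A", "B"}

    def test_null_cohort_profiles_identical_across_groups(self):
        spec = CohortSpec(n_per_group=2, session_duration_s=5.0, seed=19)
        prof = default_profiles()["western"]
        cohort = generate_cohort(spec, prof, prof, injected_effect=None)
        for truth in cohort.ground_truth.values():
            assert truth.injected_effect is None

    def test_injected_effect_reaches_group_b_only(self):
        spec = CohortSpec(n_per_group=2, session_duration_s=5.0, seed=20)
        prof = default_profiles()["western"]
        eff = InjectedEffect(center_deg=(5.5, 9.8), weight=0.3)
        cohort = generate_cohort(spec, prof, prof, injected_effect=eff)
        for (pid, _), truth in cohort.ground_truth.items():
            if pid.startswith("B"):
                assert truth.injected_effect is eff
            else:
                assert truth.injected_effect is None

    def test_trait_scores_within_instrument_ranges(self):
        spec = CohortSpec(n_per_group=10, session_duration_s=2.0, seed=21)
        prof = default_profiles()["western"]
        cohort = generate_cohort(spec, prof, prof)
        assert cohort.traits["aq"].between(0, 50).all()
        assert cohort.traits["lsas"].between(0, 144).all()

    def test_profile_validation(self):
        with pytest.raises(InvalidArgumentError):
            GazeProfile(components=(((5, 5), 1.0, 0.5),),
                        off_face_weight=0.2)  # sums to 0.7
        with pytest.raises(InvalidArgumentError):
            CohortSpec(n_per_group=1)
        with pytest.raises(InvalidArgumentError):
            CohortSpec(loss_rate=1.0)

    def test_with_off_face_rescales_exactly(self):
        prof = with_off_face(default_profiles()["western"], 0.5)
        assert prof.off_face_weight == 0.5
        assert sum(w for _, _, w in prof.components) == pytest.approx(0.5)


class TestDistributionalFidelity:
    def test_template_samples_match_generating_mixture(self):
        """Marginal distributions of 50,000 generated on-face points match
        an independent construction of the same mixture (KS distance)."""
        profile = default_profiles()["western"]
        rng = np.random.default_rng(22)
        pts = sample_template_points(profile, 50_000, rng) * 0.1  # -> deg
        # independent construction: explicit per-component draws
        rng2 = np.random.default_rng(23)
        weights = np.array([w for _, _, w in profile.components])
        weights = weights / weights.sum()
        parts = []
        counts = rng2.multinomial(50_000, weights)
        for (center, spread, _), n in zip(profile.components, counts):
            parts.append(rng2.normal(center, spread, size=(n, 2)))
        ref = np.clip(np.concatenate(parts), 0, [11 - 1e-9, 14 - 1e-9])
        for axis in (0, 1):
            d = sps.ks_2samp(pts[:, axis], ref[:, axis]).statistic
            assert d < 0.02

    def test_schedule_covers_session_and_alternates(self):
        sched = make_speech_schedule(60.0, seed=24)
        turns = sched.turns
        assert turns[0][1] == 0.0
        assert turns[-1][2] == pytest.approx(60_000.0)
        for (s1, _, e1), (s2, b2, _) in zip(turns, turns[1:]):
            assert e1 == b2
            assert s1 != s2
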