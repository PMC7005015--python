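"""Template remapping, density accumulation, smoothing, t-maps, clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dyadgaze import (AnalysisConfig, DensityMap, FaceBox, FaceTemplate,
                      InsufficientDataError, accumulate_density,
                      find_clusters, forward_map, pixelwise_t,
                      remap_to_template, smooth_map)

from oracles import flood_fill_clusters

TEMPLATE = FaceTemplate()
PARA = FaceBox(frame=0, vertices=[[100, 100], [320, 140],
                                  [360, 420], [140, 380]])


def random_convex_quad(rng):
    """Random convex quadrilateral via angular-sorted points on a disc."""
    while True:
        ang = np.sort(rng.uniform(0, 2 * np.pi, 4))
        if np.all(np.diff(ang) > 0.3) and ang[-1] - ang[0] < 2 * np.pi - 0.3:
            r = rng.uniform(80, 200, 4)
            c = rng.uniform([300, 300], [900, 600])
            pts = c + np.column_stack([r * np.cos(ang), r * np.sin(ang)])
            try:
                return FaceBox(frame=0, vertices=pts)
            except Exception:
                continue


class TestRemap:
    def test_corners_anchor_to_template_corners(self):
        v = PARA.vertices
        np.testing.assert_allclose(remap_to_template(v[0], PARA), [0, 0],
                                   atol=1e-9)
        np.testing.assert_allclose(remap_to_template(v[2], PARA), [110, 140],
                                   atol=1e-9)
        np.testing.assert_allclose(remap_to_template(v[1], PARA), [110, 0],
                                   atol=1e-9)
        np.testing.assert_allclose(remap_to_template(v[3], PARA), [0, 140],
                                   atol=1e-9)

    def test_parallelogram_centroid_maps_to_template_center(self):
        box = FaceBox(frame=0, vertices=[[100, 100], [300, 150],
                                         [340, 450], [140, 400]])
        np.testing.assert_allclose(remap_to_template(box.centroid, box),
                                   [55, 70], atol=1e-9)

    def test_outside_point_returns_none(self):
        assert remap_to_template([900.0, 900.0], PARA) is None

    def test_inverse_consistency_on_random_quads(self):
        """remap followed by the forward bilinear map returns the original
        scene point to numerical precision."""
        rng = np.random.default_rng(31)
        for _ in range(20):
            box = random_convex_quad(rng)
            w = rng.dirichlet(np.ones(4), size=500)
            pts = w @ box.vertices
            for p in pts:
                tp = remap_to_template(p, box, TEMPLATE)
                assert tp is not None
                back = forward_map(tp, box, TEMPLATE)
                np.testing.assert_allclose(back, p, atol=1e-6)


class TestAccumulate:
    def fixation_frame(self, rows):
        return pd.DataFrame([
            {"participant": "P1", "task": "introduction",
             "t_start_ms": t0, "t_end_ms": t1, "x_px": x, "y_px": y,
             "frame": 0, "label": lab, "dispersion_deg": 0.1,
             "duration_ms": t1 - t0}
            for t0, t1, x, y, lab in rows])

    def test_single_fixation_deposits_duration_at_center(self):
        box = FaceBox(frame=0, vertices=[[100, 100], [300, 150],
                                         [340, 450], [140, 400]])
        cx, cy = box.centroid
        dmap = accumulate_density(
            self.fixation_frame([(0, 200, cx, cy, "upper")]), {0: box})
        assert dmap.total_mass == 200.0
        assert dmap.values[70, 55] == 200.0
        assert np.count_nonzero(dmap.values) == 1
        assert not dmap.missing

    def test_off_face_contributes_nothing(self):
        dmap = accumulate_density(
            self.fixation_frame([(0, 500, 10, 10, "outside")]), {0: PARA})
        assert dmap.total_mass == 0.0
        assert dmap.missing

    def test_peak_near_generating_center_on_synthetic_session(self):
        """Accumulated map peaks within 1 degree of a single-component
        profile's center at ~2,000 fixations."""
        from dyadgaze.synthetic import (GazeProfile, generate_face_track,
                                        sample_template_points)
        rng = np.random.default_rng(32)
        profile = GazeProfile(components=(((5.5, 9.8), 1.0, 1.0),))
        pts = sample_template_points(profile, 2000, rng)
        grid = np.zeros((140, 110))
        np.add.at(grid, (np.minimum(pts[:, 1].astype(int), 139),
                         np.minimum(pts[:, 0].astype(int), 109)), 1.0)
        smoothed = smooth_map(DensityMap(grid))
        peak = np.unravel_index(np.argmax(smoothed.values),
                                smoothed.values.shape)
        dist_deg = np.hypot((peak[1] - 55) * 0.1, (peak[0] - 98) * 0.1)
        assert dist_deg <= 1.0


class TestSmoothing:
    def test_point_mass_symmetric_with_max_at_center(self):
        grid = np.zeros((140, 110))
        grid[70, 55] = 1.0
        out = smooth_map(DensityMap(grid), normalize=False)
        assert out.values[70, 55] == out.values.max()
        np.testing.assert_allclose(out.values[70, 55 + 10],
                                   out.values[70, 55 - 10], rtol=1e-9)
        np.testing.assert_allclose(out.values[70 + 10, 55],
                                   out.values[70 - 10, 55], rtol=1e-9)

    def test_mass_conserved_even_at_boundary(self):
        rng = np.random.default_rng(33)
        grid = np.zeros((140, 110))
        # deposit right on the corner, where truncation is worst
        grid[0, 0] = 3.0
        grid[139, 109] = 2.0
        grid[rng.integers(0, 140, 50), rng.integers(0, 110, 50)] += 1.0
        before = grid.sum()
        out = smooth_map(DensityMap(grid), normalize=False)
        assert out.total_mass == pytest.approx(before, rel=1e-9)

    def test_normalized_map_has_unit_mass(self):
        grid = np.random.default_rng(34).uniform(0, 1, (140, 110))
        out = smooth_map(DensityMap(grid))
        assert out.total_mass == pytest.approx(1.0)

    def test_matches_closed_form_gaussian_in_interior(self):
        """A point mass whose kernel support lies fully inside the grid
        smooths to the analytic 2-D Gaussian (0.5 deg -> sigma = 5 px, so
        the 4-sigma truncation radius of 20 px stays interior)."""
        cfg = AnalysisConfig(kernel_width_deg=0.5)
        grid = np.zeros((140, 110))
        grid[70, 55] = 1.0
        out = smooth_map(DensityMap(grid), cfg, normalize=False)
        sigma = 5.0
        yy, xx = np.mgrid[60:81, 45:66]
        analytic = (1.0 / (2 * np.pi * sigma ** 2)
                    * np.exp(-((xx - 55) ** 2 + (yy - 70) ** 2)
                             / (2 * sigma ** 2)))
        # sampled-and-normalized discrete kernel vs continuous density
        np.testing.assert_allclose(out.values[60:81, 45:66], analytic,
                                   rtol=2e-3)

    def test_linearity_commutes_with_addition(self):
        rng = np.random.default_rng(35)
        a = DensityMap(rng.uniform(0, 1, (140, 110)))
        b = DensityMap(rng.uniform(0, 1, (140, 110)))
        sum_then_smooth = smooth_map(DensityMap(a.values + b.values),
                                     normalize=False).values
        smooth_then_sum = (smooth_map(a, normalize=False).values
                           + smooth_map(b, normalize=False).values)
        np.testing.assert_allclose(sum_then_smooth, smooth_then_sum,
                                   rtol=1e-9)

    def test_fwhm_interpretation_narrows_kernel(self):
        grid = np.zeros((140, 110))
        grid[70, 55] = 1.0
        sigma_mode = smooth_map(DensityMap(grid),
                                AnalysisConfig(kernel_width_is_fwhm=False),
                                normalize=False)
        fwhm_mode = smooth_map(DensityMap(grid),
                               AnalysisConfig(kernel_width_is_fwhm=True),
                               normalize=False)
        assert fwhm_mode.values[70, 55] > sigma_mode.values[70, 55]


def maps_from(arrays):
    return [DensityMap(np.asarray(a, float)) for a in arrays]


class TestPixelwiseT:
    def test_identical_sets_give_zero_t(self):
        rng = np.random.default_rng(36)
        base = rng.uniform(0, 1, (3, 8, 6))
        t, t_crit, df = pixelwise_t(maps_from(base), maps_from(base.copy()))
        np.testing.assert_array_equal(t, 0.0)
        assert df == 4
        assert t_crit == pytest.approx(sps.t.ppf(0.995, 4))

    def test_swapping_groups_negates_t(self):
        rng = np.random.default_rng(37)
        a = rng.uniform(0, 1, (4, 8, 6))
        b = rng.uniform(0, 1, (4, 8, 6))
        t_ab, _, _ = pixelwise_t(maps_from(a), maps_from(b))
        t_ba, _, _ = pixelwise_t(maps_from(b), maps_from(a))
        np.testing.assert_allclose(t_ab, -t_ba, atol=1e-12)

    def test_hand_computed_two_sample_formula(self):
        a = maps_from([[[1.0]], [[3.0]]])
        b = maps_from([[[6.0]], [[10.0]]])
        t, _, df = pixelwise_t(a, b)
        # means 2 vs 8, ss 2 + 8, sp2 = 10/2 = 5, se = sqrt(5*(1)) -> t
        assert df == 2
        assert t[0, 0] == pytest.approx((2 - 8) / np.sqrt(5.0 * 1.0))

    def test_zero_variance_sentinels(self):
        a = maps_from([[[1.0, 5.0]], [[1.0, 5.0]]])
        b = maps_from([[[1.0, 2.0]], [[1.0, 2.0]]])
        t, t_crit, _ = pixelwise_t(a, b)
        assert t[0, 0] == 0.0
        assert np.isposinf(t[0, 1]) and t[0, 1] > t_crit

    def test_insufficient_maps_rejected(self):
        with pytest.raises(InsufficientDataError):
            pixelwise_t(maps_from([[[1.0]]]), maps_from([[[1.0]], [[2.0]]]))


class TestFindClusters:
    def test_subthreshold_map_yields_nothing(self):
        assert find_clusters(np.zeros((10, 10)), t_crit=2.0) == []

    def test_block_cluster_size(self):
        t = np.zeros((10, 10))
        t[3:6, 4:7] = 5.0
        clusters = find_clusters(t, t_crit=2.0)
        assert len(clusters) == 1
        assert clusters[0].size == 9
        assert clusters[0].sign == "positive"

    def test_signed_clusters_separated(self):
        t = np.zeros((10, 10))
        t[1:3, 1:3] = 4.0
        t[7:9, 7:9] = -4.0
        clusters = find_clusters(t, t_crit=2.0)
        assert {c.sign for c in clusters} == {"positive", "negative"}

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(38)
        for _ in range(20):
            t = rng.normal(0, 1.6, (30, 24))
            clusters = find_clusters(t, t_crit=2.0,
                                     connectivity=connectivity)
            expected = (flood_fill_clusters(t > 2.0, connectivity)
                        + flood_fill_clusters(t < -2.0, connectivity))
            got = {frozenset(map(tuple, c.pixels)) for c in clusters}
            assert got == {frozenset(c) for c in expected}
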