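"""Morphometric operations against independent geometric oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import draw as skdraw

import flowmorph as fm
from conftest import label_image_from_cells


def moment_ellipse_oracle(mask):
    """Independent second-moment computation on the raw pixel set."""
    ys, xs = np.nonzero(mask)
    x = xs - xs.mean()
    y = -(ys - ys.mean())
    c = np.array([
        [np.mean(x * x) + 1 / 12, np.mean(x * y)],
        [np.mean(x * y), np.mean(y * y) + 1 / 12],
    ])
    lam = np.linalg.eigvalsh(c)
    return 2 * np.sqrt(lam[1]), 2 * np.sqrt(lam[0])


class TestEllipseFit:
    def test_rectangle_matches_moment_oracle(self):
        mask = np.zeros((40, 40), bool)
        mask[15:25, 10:30] = True  # 20 wide, 10 tall
        fit = fm.ellipse_fit(mask)
        a0, b0 = moment_ellipse_oracle(mask)
        assert fit.theta_deg == pytest.approx(0.0, abs=1e-6)
        assert fit.a / fit.b == pytest.approx(2.0, abs=0.01)
        assert (fit.a, fit.b) == pytest.approx((a0, b0), abs=1e-9)

    def test_rotated_rectangle_theta_90(self):
        mask = np.zeros((40, 40), bool)
        mask[10:30, 15:25] = True
        assert fm.ellipse_fit(mask).theta_deg == pytest.approx(90.0, abs=1e-6)

    def test_disc_is_isotropic_and_flagged(self):
        mask = np.zeros((61, 61), bool)
        rr, cc = skdraw.disk((30, 30), 25)
        mask[rr, cc] = True
        fit = fm.ellipse_fit(mask)
        assert (fit.a - fit.b) / fit.a < 0.02
        assert not fit.theta_stable

    def test_too_few_pixels_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[2, 2:5] = True
        with pytest.raises(ValueError, match="5"):
            fm.ellipse_fit(mask)

    @settings(deadline=None, max_examples=25)
    @given(theta=st.floats(0, 179), ab=st.tuples(st.floats(8, 20), st.floats(4, 8)))
    def test_recovers_drawn_ellipse_orientation(self, theta, ab):
        a, b = max(ab), min(ab)
        if a / b < 1.6:
            return  # raster angle noise blows up near isotropy
        mask = np.zeros((64, 64), bool)
        rr, cc = skdraw.ellipse(32, 32, b, a, rotation=np.radians(theta), shape=(64, 64))
        mask[rr, cc] = True
        fit = fm.ellipse_fit(mask)
        assert float(fm.fold_axial_deg(fit.theta_deg - theta)) < 5.0


class TestEccentricity:
    @pytest.mark.parametrize(
        "a,b,expected", [(5, 3, 0.8), (5, 4, 0.6), (7, 7, 0.0), (1, 1, 0.0)]
    )
    def test_exact_values(self, a, b, expected):
        assert fm.eccentricity((a, b)) == pytest.approx(expected, abs=1e-12)

    def test_b_greater_than_a_rejected(self):
        with pytest.raises(ValueError):
            fm.eccentricity((3, 5))


class TestOrientationSummary:
    def _fits(self, thetas):
        return [fm.EllipseFit((0, 0), 2, 1, t) for t in thetas]

    def test_one_angle_per_bin(self, flow_x):
        s = fm.orientation_summary(self._fits([5, 15, 25, 35, 45, 55, 65, 75, 85]), flow_x)
        assert np.allclose(s.histogram_pct, 100 / 9)
        assert s.aligned_fraction_pct == pytest.approx(100 / 3)

    def test_all_aligned(self, flow_x):
        s = fm.orientation_summary(self._fits([0.0] * 7), flow_x)
        assert s.histogram_pct[0] == 100.0
        assert s.aligned_fraction_pct == 100.0

    def test_boundary_30_counts_as_not_aligned_and_90_in_last_bin(self, flow_x):
        s = fm.orientation_summary(self._fits([30.0, 90.0]), flow_x)
        assert s.aligned_fraction_pct == 0.0
        assert s.histogram_pct[-1] == 50.0

    def test_empty_rejected(self, flow_x):
        with pytest.raises(ValueError):
            fm.orientation_summary([], flow_x)

    @settings(deadline=None, max_examples=20)
    @given(st.lists(st.floats(0, 179.99), min_size=1, max_size=40),
           st.floats(-180, 180))
    def test_histogram_sums_to_100_any_flow(self, thetas, flow_deg):
        flow = fm.FlowField((np.cos(np.radians(flow_deg)), np.sin(np.radians(flow_deg))))
        s = fm.orientation_summary(self._fits(thetas), flow)
        assert s.histogram_pct.sum() == pytest.approx(100.0)
        assert np.all((s.angles_deg >= 0) & (s.angles_deg <= 90))


class TestJunctionLinearization:
    def test_convex_shapes_score_one(self):
        rect = np.zeros((40, 60), bool)
        rect[10:30, 10:50] = True
        assert fm.junction_linearization_index(rect).jli == pytest.approx(1.0, abs=0.02)
        disc = np.zeros((70, 70), bool)
        rr, cc = skdraw.disk((35, 35), 30)
        disc[rr, cc] = True
        assert fm.junction_linearization_index(disc).jli == pytest.approx(1.0, abs=0.02)

    def test_plus_sign_matches_polygon_oracle(self):
        mask = np.zeros((80, 80), bool)
        mask[10:70, 30:50] = True
        mask[30:50, 10:70] = True
        # exact geometry of two crossing 60x20 bars:
        # contour 12 edges of 20; hull = 4 caps of 20 + 4 diagonals sqrt(800)
        oracle = (12 * 20.0) / (4 * 20.0 + 4 * np.sqrt(800.0))
        rec = fm.junction_linearization_index(mask)
        assert rec.jli == pytest.approx(oracle, abs=0.03)

    def test_holes_filled_with_warning(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        mask[12:18, 12:18] = False
        with pytest.warns(UserWarning, match="holes"):
            rec = fm.junction_linearization_index(mask)
        assert rec.jli == pytest.approx(1.0, abs=0.02)
        assert rec.area_px == 400

    def test_multi_component_rejected(self):
        mask = np.zeros((30, 30), bool)
        mask[2:10, 2:10] = True
        mask[20:28, 20:28] = True
        with pytest.raises(ValueError, match="components"):
            fm.junction_linearization_index(mask)

    def test_jli_nondecreasing_in_boundary_irregularity(self):
        """Rougher generated junctions must raise the mean index."""
        means = []
        for irr in (0.0, 2.0, 5.0):
            cfg = fm.SceneConfig(n_cells=60, width=768, height=768, seed=11,
                                 junction_irregularity=irr)
            scene = fm.make_monolayer(cfg)
            table = fm.cell_shape_table(label_image_from_cells(scene.channels["cells"]))
            assert len(table) >= 25
            means.append(table.jli.mean())
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0] + 0.005


class TestGolgiAngle:
    @pytest.mark.parametrize(
        "offset_rc,expected",
        [((0, -1), 0.0),    # upstream (against flow)
         ((0, +1), 180.0),  # downstream
         ((+1, 0), 90.0),   # CCW side in the math frame (row +1 => y = -1)
         ((-1, 0), 270.0)],
    )
    def test_convention_flow_plus_x(self, offset_rc, expected, flow_x):
        nucleus = (10.0, 10.0)
        golgi = (10.0 + offset_rc[0], 10.0 + offset_rc[1])
        assert fm.golgi_angle(nucleus, golgi, flow_x) == pytest.approx(expected)

    def test_coincident_centroids_flagged_nan(self, flow_x):
        with pytest.warns(UserWarning, match="unpolarized"):
            assert np.isnan(fm.golgi_angle((5, 5), (5, 5), flow_x))

    @settings(deadline=None, max_examples=30)
    @given(psi=st.floats(0, 359.9), rot=st.floats(-180, 180))
    def test_rotation_invariance(self, psi, rot):
        """Rotating flow and displacement together preserves the angle."""
        flow = fm.FlowField((1, 0))
        d = np.radians(psi)
        golgi = (10 + 3 * np.sin(d), 10 - 3 * np.cos(d))
        base = fm.golgi_angle((10, 10), golgi, flow)
        flow_r = flow.rotated(rot)
        t = np.radians(rot)
        dx, dy = golgi[1] - 10, -(golgi[0] - 10)
        dx2 = np.cos(t) * dx - np.sin(t) * dy
        dy2 = np.sin(t) * dx + np.cos(t) * dy
        rotated = fm.golgi_angle((10, 10), (10 - dy2, 10 + dx2), flow_r)
        diff = abs((rotated - base + 180) % 360 - 180)
        assert diff < 1e-6


class TestCircularSummary:
    def test_simple_mean_and_wraparound(self):
        assert fm.circular_summary([10, 20, 30]).mean_deg == pytest.approx(20.0)
        assert fm.circular_summary([350, 10]).mean_deg == pytest.approx(0.0, abs=1e-9)

    def test_identical_angles_sd_zero(self):
        s = fm.circular_summary([0, 0, 0])
        assert s.resultant_length == pytest.approx(1.0)
        assert s.sd_deg == 0.0

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(0, 360), min_size=1, max_size=30))
    def test_sd_matches_resultant_vector_oracle(self, angles):
        s = fm.circular_summary(angles)
        rad = np.radians(angles)
        rbar = np.hypot(np.cos(rad).mean(), np.sin(rad).mean())
        assert s.resultant_length == pytest.approx(rbar, abs=1e-12)
        if 1e-9 < rbar < 1.0:
            assert s.sd_deg == pytest.approx(np.degrees(np.sqrt(-2 * np.log(rbar))), abs=1e-9)

    def test_vanishing_resultant_flags_undefined_mean(self):
        s = fm.circular_summary([0, 90, 180, 270])
        assert not s.mean_defined
        assert np.isnan(s.mean_deg)

    def test_axial_doubling(self):
        # axes at 170 and 10 deg straddle 0: axial mean is 0, not 90
        s = fm.circular_summary([170.0, 10.0], axial=True)
        assert s.mean_deg == pytest.approx(0.0, abs=1e-9) or s.mean_deg == pytest.approx(180.0)

    def test_angular_deviation_variant(self):
        s = fm.circular_summary([0, 40], sd_kind="angular")
        rbar = s.resultant_length
        assert s.sd_deg == pytest.approx(np.degrees(np.sqrt(2 * (1 - rbar))), abs=1e-9)


class TestRoseHistogram:
    def test_opposite_angles_land_in_opposite_sectors(self):
        counts = fm.rose_histogram([0, 180], bin_deg=20)
        assert counts[0] == 1 and counts[9] == 1 and counts.sum() == 2

    def test_empty_input_all_zero(self):
        counts = fm.rose_histogram([], bin_deg=20)
        assert counts.sum() == 0 and len(counts) == 18

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(ValueError):
            fm.rose_histogram([0], bin_deg=25)

    def test_von_mises_modal_sector(self):
        rng = np.random.default_rng(42)
        angles = np.degrees(rng.vonmises(np.radians(90), 8.0, 1000)) % 360
        counts = fm.rose_histogram(angles, bin_deg=20)
        assert 90 // 20 == np.argmax(counts)
        assert counts.sum() == 1000


class TestColourAndAreaFractions:
    def test_pure_blue_and_pure_red(self):
        blue = np.zeros((8, 8, 3), np.uint8)
        blue[..., 2] = 255
        assert fm.hsv_blue_fraction(blue) == 1.0
        red = np.zeros((8, 8, 3), np.uint8)
        red[..., 0] = 255
        assert fm.hsv_blue_fraction(red) == 0.0

    def test_gray_pixels_count_non_blue(self):
        gray = np.full((4, 4, 3), 128, np.uint8)
        assert fm.hsv_blue_fraction(gray) == 0.0

    def test_synthetic_tissue_fraction_exact(self):
        scene = fm.make_stained_tissue(0.3, seed=3)
        frac = fm.hsv_blue_fraction(scene.channels["rgb"], scene.channels["roi"])
        assert frac == scene.truth.blue_fraction_realized[0]

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            fm.hsv_blue_fraction(np.zeros((4, 4, 3), np.uint8), np.zeros((4, 4), bool))

    def test_object_density(self):
        # 10 objects in a 1 mm^2 field (1000x1000 px at 1 um/px)
        lab = np.zeros((1000, 1000), np.int32)
        for k in range(10):
            lab[50 * k + 5 : 50 * k + 15, 5:15] = k + 1
        assert fm.object_density(fm.LabelImage(lab, 1.0)) == pytest.approx(10.0)

    def test_density_from_generated_scene(self):
        scene = fm.make_monolayer(fm.SceneConfig(n_cells=37, seed=8))
        lab = fm.segment_nuclei(scene.channels["nuclei"])
        area_mm2 = 512 * 512 / 1e6
        assert fm.object_density(lab) == pytest.approx(37 / area_mm2)


class TestVesselGeometry:
    def test_constant_band_exact(self):
        scene = fm.make_vessel(12, length_px=300, noise=0.0)
        geom = fm.vessel_diameter(scene.channels["mask"])
        assert geom.mean_diameter_px == 12.0

    def test_noisy_phantom_within_half_pixel(self):
        scene = fm.make_vessel(12, length_px=400, noise=2.0, seed=7)
        geom = fm.vessel_diameter(scene.channels["mask"])
        assert abs(geom.mean_diameter_px - 12.0) < 0.5

    def test_vertical_tube_auto_axis(self):
        scene = fm.make_vessel(10, length_px=300, noise=0.0)
        geom = fm.vessel_diameter(scene.channels["mask"].T)
        assert geom.axis == "y"
        assert geom.mean_diameter_px == 10.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fm.vessel_diameter(np.zeros((20, 20), bool))

    def test_non_tubular_warns(self):
        disc = np.zeros((60, 60), bool)
        rr, cc = skdraw.disk((30, 30), 20)
        disc[rr, cc] = True
        with pytest.warns(UserWarning, match="tubular"):
            fm.vessel_diameter(disc)

    def test_skeleton_mode_agrees_on_straight_tube(self):
        scene = fm.make_vessel(14, length_px=300, noise=0.0)
        chord = fm.vessel_diameter(scene.channels["mask"], mode="chord")
        skel = fm.vessel_diameter(scene.channels["mask"], mode="skeleton")
        assert abs(chord.mean_diameter_px - skel.mean_diameter_px) < 1.5


class TestSegmentCounts:
    def test_single_tube_counts(self):
        scene = fm.make_tube_stack([8.0], n_slices=200)
        counts = fm.segment_counts_by_diameter(scene.channels["stack"], [6, 12])
        assert counts.totals.tolist() == [200]

    def test_three_tubes_binned_by_diameter(self):
        scene = fm.make_tube_stack([4.0, 8.0, 16.0], n_slices=200)
        counts = fm.segment_counts_by_diameter(scene.channels["stack"], [2, 6, 12, 20])
        assert counts.totals.tolist() == [200, 200, 200]
        assert counts.per_slice.shape == (200, 3)
        assert (counts.per_slice == 1).all()

    def test_empty_stack_zero_counts(self):
        counts = fm.segment_counts_by_diameter(np.zeros((5, 16, 16), int), [0, 10])
        assert counts.totals.tolist() == [0]

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValueError):
            fm.segment_counts_by_diameter(np.zeros((2, 8, 8), int), [10, 5])


class TestDepthProfile:
    def test_two_cells_equal_peaks_and_surface_exclusion(self):
        # constructed stack: equal-area discs at depth 0 and 50 um (z_step 2)
        stack = np.zeros((30, 64, 64), np.int32)
        rr, cc = skdraw.disk((20, 20), 5)
        stack[0, rr, cc] = 1
        rr, cc = skdraw.disk((44, 44), 5)
        stack[25, rr, cc] = 2
        prof = fm.depth_profile(stack, z_step_um=2.0)
        nz = np.nonzero(prof.area_um2)[0]
        assert nz.tolist() == [0, 25]
        assert prof.area_um2[0] == prof.area_um2[25]
        assert prof.mean_sprout_length_um == 50.0
        assert prof.n_invading == 1

    def test_all_cells_at_surface(self):
        stack = np.zeros((10, 32, 32), np.int32)
        stack[0, 5:10, 5:10] = 1
        prof = fm.depth_profile(stack, z_step_um=2.0)
        assert prof.mean_sprout_length_um == 0.0
        assert prof.n_invading == 0

    def test_generated_point_mass_recovered(self):
        scene = fm.make_sprout_stack(10, {"kind": "point", "value": 20.0}, seed=4)
        prof = fm.depth_profile(scene.channels["stack"], z_step_um=scene.z_step_um)
        assert prof.mean_sprout_length_um == pytest.approx(20.0, abs=0.5)
        assert prof.n_invading == 10

    def test_area_conservation(self):
        scene = fm.make_sprout_stack(6, {"kind": "uniform", "low": 10, "high": 50}, seed=5)
        prof = fm.depth_profile(scene.channels["stack"], z_step_um=scene.z_step_um)
        assert prof.area_um2.sum() == (scene.channels["stack"] > 0).sum()

    def test_invalid_z_step_rejected(self):
        with pytest.raises(ValueError):
            fm.depth_profile(np.zeros((2, 4, 4), int), z_step_um=0)
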