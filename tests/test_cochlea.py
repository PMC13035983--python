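"""Cochlear measurement chain: calibration, diameters, height, duct lengths,
modiolus-canal angles, and ground-truth recovery on phantoms."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from labyrinthometry import (
    VoxelCloud,
    angle_between_vectors,
    basal_long_diameter,
    basal_short_diameter,
    calibrate,
    cochlear_height,
    derived_lengths,
    fit_plane,
    measure_cochlea,
    modiolus_canal_angles,
    round_window_center,
)


@pytest.fixture(scope="module")
def cochlea_cloud(request):
    default_clouds = request.getfixturevalue("default_clouds")
    return default_clouds["cochlea"]


@pytest.fixture(scope="module")
def cochlea_truth(request):
    _, truth = request.getfixturevalue("default_assembly")
    return truth


class TestCalibrate:
    def test_recovers_modiolar_axis_within_3deg(self, cochlea_cloud, cochlea_truth):
        cal = calibrate(cochlea_cloud)
        err = angle_between_vectors(
            cal.modiolar_axis, cochlea_truth.modiolar_axis, fold=True
        )
        assert err < 3.0

    def test_rotation_equivariance(self, cochlea_cloud, cochlea_truth):
        R = Rotation.from_rotvec([0.5, -0.2, 0.9]).as_matrix()
        rotated = VoxelCloud(
            cochlea_cloud.points_mm @ R.T, "cochlea", cochlea_cloud.spacing_mm
        )
        cal = calibrate(rotated)
        err = angle_between_vectors(
            cal.modiolar_axis, R @ cochlea_truth.modiolar_axis, fold=True
        )
        assert err < 3.0

    def test_flat_disc_still_calibrates(self, rng):
        r = np.sqrt(rng.uniform(0, 1, 500)) * 4.0
        th = rng.uniform(0, 2 * np.pi, 500)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(500)])
        cal = calibrate(pts)
        assert abs(cal.modiolar_axis @ [0, 0, 1]) > 0.999999

    def test_small_cloud_rejected(self, rng):
        with pytest.raises(ValueError, match="100"):
            calibrate(rng.normal(size=(20, 3)))


class TestRoundWindow:
    def test_tie_broken_by_largest_y(self):
        pts = np.array([[0.0, 0.0], [2.0, 1.0], [2.0, -1.0]])
        np.testing.assert_allclose(round_window_center(pts), [2.0, 1.0])

    def test_single_point(self):
        np.testing.assert_allclose(round_window_center([[1.5, -0.5]]), [1.5, -0.5])

    def test_on_basal_outer_end_of_phantom(self, cochlea_cloud, cochlea_truth):
        cal = calibrate(cochlea_cloud)
        rw = round_window_center(cal.coords2)
        truth_planar = cal.frame.to_local(cochlea_truth.round_window_mm[None, :])[0][:2]
        assert np.linalg.norm(rw - truth_planar) < 0.3


class TestBasalDiameters:
    def test_bld_three_four_five(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        bld, far = basal_long_diameter(pts, np.array([0.0, 0.0]))
        assert bld == pytest.approx(5.0)
        np.testing.assert_allclose(far, [3.0, 4.0])

    def test_bld_zero_for_coincident_points(self):
        pts = np.full((5, 2), 1.0)
        bld, _ = basal_long_diameter(pts, np.array([1.0, 1.0]))
        assert bld == 0.0

    def test_bld_matches_brute_force_chord_through_rw(self, rng):
        # the BLD from the round-window point equals the max distance from
        # that point, checked against an all-pairs scan
        pts = rng.uniform(-4, 4, size=(1500, 2))
        rw = round_window_center(pts)
        bld, _ = basal_long_diameter(pts, rw)
        brute = max(np.linalg.norm(p - rw) for p in pts)
        assert bld == pytest.approx(brute, abs=1e-12)

    def test_bld_recovers_phantom_chord(self, cochlea_cloud, cochlea_truth):
        cal = calibrate(cochlea_cloud)
        rw = round_window_center(cal.coords2)
        bld, _ = basal_long_diameter(cal.coords2, rw)
        assert bld == pytest.approx(cochlea_truth.basal_long_diameter_mm, abs=0.2)

    def test_bsd_on_dense_ellipse(self, rng):
        th = rng.uniform(0, 2 * np.pi, 20000)
        r = np.sqrt(rng.uniform(0, 1, 20000))
        pts = np.column_stack([4.5 * r * np.cos(th), 3.25 * r * np.sin(th)])
        rw = round_window_center(pts)
        bld, far = basal_long_diameter(pts, rw)
        bsd = basal_short_diameter(pts, rw, far, 0.1)
        assert bsd == pytest.approx(6.5, abs=0.15)

    def test_bsd_zero_when_collinear(self):
        x = np.linspace(0, 5, 200)
        pts = np.column_stack([x, np.zeros_like(x)])
        bsd = basal_short_diameter(pts, pts[0], pts[-1], 0.1)
        assert bsd == pytest.approx(0.0, abs=1e-12)

    def test_bsd_stable_under_bin_halving(self, rng):
        th = rng.uniform(0, 2 * np.pi, 30000)
        r = np.sqrt(rng.uniform(0, 1, 30000))
        pts = np.column_stack([4.5 * r * np.cos(th), 3.25 * r * np.sin(th)])
        rw = round_window_center(pts)
        bld, far = basal_long_diameter(pts, rw)
        b1 = basal_short_diameter(pts, rw, far, 0.1)
        b2 = basal_short_diameter(pts, rw, far, 0.05)
        assert abs(b1 - b2) < 0.2

    def test_coincident_rw_far_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            basal_short_diameter(np.zeros((5, 2)), np.zeros(2), np.zeros(2), 0.1)


class TestCochlearHeight:
    def test_extent_mode_arithmetic(self):
        coords3 = np.zeros((3, 3))
        coords3[:, 2] = [-2.03, 0.0, 2.03]
        assert cochlear_height(coords3) == pytest.approx(4.06)

    def test_flat_gives_zero_in_both_modes(self):
        coords3 = np.zeros((10, 3))
        assert cochlear_height(coords3, mode="extent") == 0.0
        assert cochlear_height(coords3, mode="absolute") == 0.0

    def test_absolute_mode_is_half_extent_for_centered_coords(self):
        z = np.linspace(-2.0, 2.0, 101)
        coords3 = np.column_stack([np.zeros(101), np.zeros(101), z])
        assert cochlear_height(coords3, mode="absolute") == pytest.approx(2.0)

    def test_phantom_height_recovered(self, cochlea_cloud, cochlea_truth):
        cal = calibrate(cochlea_cloud)
        ch = cochlear_height(cal.coords3)
        assert ch == pytest.approx(cochlea_truth.cochlear_height_mm, abs=0.15)


class TestDerivedLengths:
    @pytest.mark.parametrize(
        "bld, cdl, tl2, btl",
        [
            (9.08, 33.77, 29.49, 19.63),  # affected-ear scale
            (8.98, 33.36, 29.13, 19.39),  # healthy-ear scale
        ],
    )
    def test_reference_values_to_2dp(self, bld, cdl, tl2, btl):
        c, t, b = derived_lengths(bld)
        assert round(c, 2) == cdl
        assert round(t, 2) == tl2
        assert round(b, 2) == btl

    def test_limits_at_bld_one(self):
        c, t, b = derived_lengths(1.0 + 1e-9)
        assert t == pytest.approx(0.0, abs=1e-8)
        assert b == pytest.approx(0.0, abs=1e-8)

    def test_bld_at_most_one_rejected(self):
        with pytest.raises(ValueError, match="BLD > 1"):
            derived_lengths(0.9)

    def test_literal_sign_refused(self):
        with pytest.raises(ValueError, match="negative lengths"):
            derived_lengths(9.0, literal_sign=True)


class TestModiolusCanalAngles:
    def test_axis_parallel_to_normal_is_zero(self, rng):
        pts = np.column_stack([rng.normal(size=(60, 2)), np.zeros(60)])
        fits = {"LSC": fit_plane(pts)}
        angles = modiolus_canal_angles(np.array([0.0, 0.0, 1.0]), fits)
        assert angles["LSC"] == pytest.approx(0.0, abs=1e-9)

    def test_axis_in_plane_is_ninety(self, rng):
        pts = np.column_stack([rng.normal(size=(60, 2)), np.zeros(60)])
        fits = {"LSC": fit_plane(pts)}
        angles = modiolus_canal_angles(np.array([1.0, 0.0, 0.0]), fits)
        assert angles["LSC"] == pytest.approx(90.0, abs=1e-9)

    def test_thirty_degree_oracle(self):
        axis = np.array([0.0, 0.0, 1.0])
        normal = np.array([0.0, np.sin(np.radians(30)), np.cos(np.radians(30))])
        angle = angle_between_vectors(axis, normal, fold=True)
        assert angle == pytest.approx(30.0, abs=1e-9)


class TestMeasureCochlea:
    def test_all_fields_finite_and_invariants(self, cochlea_cloud, canal_fits):
        m = measure_cochlea(cochlea_cloud, canal_fits)
        values = [
            m.volume_mm3, m.bld_mm, m.bsd_mm, m.ch_mm, m.cdl_mm, m.tl2_mm, m.btl_mm,
            m.angle_modiolus_lsc_deg, m.angle_modiolus_psc_deg, m.angle_modiolus_ssc_deg,
        ]
        assert np.all(np.isfinite(values))
        assert m.bld_mm >= m.bsd_mm > 0
        for a in values[-3:]:
            assert 0.0 <= a <= 90.0

    def test_derived_lengths_consistent_with_bld(self, cochlea_cloud, canal_fits):
        m = measure_cochlea(cochlea_cloud, canal_fits)
        c, t, b = derived_lengths(m.bld_mm)
        assert (m.cdl_mm, m.tl2_mm, m.btl_mm) == (c, t, b)

    def test_modiolus_angles_match_phantom_construction(
        self, cochlea_cloud, canal_fits, cochlea_truth
    ):
        m = measure_cochlea(cochlea_cloud, canal_fits)
        for name, measured in [
            ("LSC", m.angle_modiolus_lsc_deg),
            ("PSC", m.angle_modiolus_psc_deg),
            ("SSC", m.angle_modiolus_ssc_deg),
        ]:
            expected = angle_between_vectors(
                cochlea_truth.modiolar_axis,
                cochlea_truth.canal_normals[name],
                fold=True,
            )
            assert measured == pytest.approx(expected, abs=1.0)

    def test_scalar_metrics_invariant_under_rigid_motion(
        self, cochlea_cloud, canal_fits, rng
    ):
        m0 = measure_cochlea(cochlea_cloud, canal_fits)
        R = Rotation.random(random_state=7).as_matrix()
        t = rng.uniform(-10, 10, 3)
        moved = VoxelCloud(
            cochlea_cloud.points_mm @ R.T + t, "cochlea", cochlea_cloud.spacing_mm
        )
        from labyrinthometry.geometry import PlaneFit

        moved_fits = {
            n: PlaneFit(R @ f.normal, R @ f.centroid_mm + t, f.rms_residual_mm)
            for n, f in canal_fits.items()
        }
        m1 = measure_cochlea(moved, moved_fits)
        assert m1.bld_mm == pytest.approx(m0.bld_mm, rel=0.02)
        assert m1.bsd_mm == pytest.approx(m0.bsd_mm, rel=0.02)
        assert m1.ch_mm == pytest.approx(m0.ch_mm, rel=0.02)
        assert m1.angle_modiolus_lsc_deg == pytest.approx(
            m0.angle_modiolus_lsc_deg, abs=2.0
        )
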