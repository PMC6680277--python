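from __future__ import annotations

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

from xrh import new_volume
from xrh.register import (
    LandmarkSet,
    elastic_register,
    fit_plane,
    match_slice,
    read_landmarks,
    registration_report,
)


class TestLandmarks:
    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "lm.csv"
        path.write_text(
            "x2d,y2d,x3d,y3d,z3d\n10,20,1.5,2.5,3.5\n30,40,4,5,6\n50,60,7,8,9\n"
        )
        lm = read_landmarks(path)
        assert len(lm) == 3
        np.testing.assert_allclose(lm.p2d[0], [10, 20])
        np.testing.assert_allclose(lm.p3d[0], [3.5, 2.5, 1.5])  # stored (z, y, x)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="columns"):
            read_landmarks(path)

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ValueError, match="three"):
            LandmarkSet(np.zeros((2, 2)), np.zeros((2, 3)))


class TestFitPlane:
    @staticmethod
    def _lm(p3d):
        p3d = np.asarray(p3d, dtype=float)
        return LandmarkSet(np.zeros((len(p3d), 2)), p3d)

    def test_axis_aligned_plane_at_z5(self):
        plane = fit_plane(self._lm([(5, 0, 0), (5, 10, 0), (5, 0, 10)]))
        normal = np.abs(plane.normal)
        np.testing.assert_allclose(normal, [1, 0, 0], atol=1e-12)
        assert plane.origin[0] == pytest.approx(5.0)

    def test_coplanar_oblique_points_have_zero_residual(self):
        n = np.array([1.0, 2.0, 2.0]) / 3.0
        u = np.array([2.0, -1.0, 0.0]) / np.sqrt(5)
        v = np.cross(n, u)
        base = np.array([10.0, 10.0, 10.0])
        pts = [base + a * u + b * v for a, b in [(0, 0), (5, 0), (0, 5), (3, 4)]]
        plane = fit_plane(self._lm(pts))
        for p in pts:
            residual = abs((np.asarray(p) - np.asarray(plane.origin)) @ plane.normal)
            assert residual < 1e-9

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            fit_plane(self._lm([(0, 0, 0), (1, 1, 1), (2, 2, 2)]))


class TestMatchSlice:
    def test_lattice_plane_returns_stored_slice(self, rng):
        vol = new_volume(rng.random((10, 12, 12)).astype(np.float32), 1.0)
        p3d = np.array([(4.0, 1.0, 1.0), (4.0, 10.0, 2.0), (4.0, 3.0, 10.0)])
        lm = LandmarkSet(np.zeros((3, 2)), p3d)
        image, plane, candidates = match_slice(
            vol, lm, offset_range=2.0, offset_step=1.0, histology=None
        )
        assert len(candidates) == 5  # offsets -2..2
        assert abs(abs(plane.normal[0]) - 1.0) < 1e-9
        # axis-aligned fit snaps to the lattice: in-bounds pixels reproduce
        # the stored z=4 slice bit-exactly, out-of-bounds pixels pad with 0
        origin = np.asarray(plane.origin)
        assert np.allclose(origin, np.round(origin))
        oz, oy, ox = (int(c) for c in np.round(origin))
        assert oz == 4
        w, h = plane.extent
        stored = vol.data[4]
        for i in range(h):
            for j in range(w):
                y, x = oy + i, ox + j
                expected = stored[y, x] if 0 <= y < 12 and 0 <= x < 12 else 0.0
                assert image[i, j] == expected

    def test_recovers_generator_plane_within_half_voxel(self, rng):
        from xrh.phantom import PhantomSpec, ball, make_geometric_phantom
        from xrh.render import PlaneSpec

        vol, _ = make_geometric_phantom(
            PhantomSpec(shape=(32, 32, 32), noise_sigma=0.0), [ball(9, (16, 16, 16))]
        )
        true_plane = PlaneSpec(
            origin=(12.0, 0.0, 0.0),
            u_axis=(0.0, 0.0, 1.0),
            v_axis=(0.0, 1.0, 0.0),
            extent=(32, 32),
        )
        pts2d = rng.uniform(4, 28, size=(6, 2))
        p3d = np.array([(12.0, y, x) for x, y in pts2d])
        lm = LandmarkSet(pts2d, p3d)
        _, plane, _ = match_slice(vol, lm)
        # same orientation and position as the generator plane
        assert abs(abs(float(np.dot(plane.normal, true_plane.normal))) - 1.0) < 1e-9
        gap = abs(float((np.asarray(plane.origin) - true_plane.origin) @ true_plane.normal))
        assert gap < 0.5

    def test_plane_outside_volume_rejected(self, rng):
        vol = new_volume(rng.random((6, 6, 6)).astype(np.float32), 1.0)
        p3d = np.array([(50.0, 0.0, 0.0), (50.0, 5.0, 0.0), (50.0, 0.0, 5.0)])
        with pytest.raises(ValueError, match="outside"):
            match_slice(vol, LandmarkSet(np.zeros((3, 2)), p3d))


class TestElasticRegister:
    def test_identity_pairs_give_identity_warp(self, rng):
        img = rng.random((24, 24))
        pts = np.array([(3.0, 3.0), (20.0, 4.0), (5.0, 19.0), (18.0, 18.0)])
        warp, warped = elastic_register(img, img, pts, pts)
        np.testing.assert_allclose(warp(pts), pts, atol=1e-9)
        np.testing.assert_allclose(warped[2:-2, 2:-2], img[2:-2, 2:-2], atol=1e-6)

    def test_translation_pairs_give_uniform_translation(self, rng):
        src = np.array([(3.0, 3.0), (20.0, 4.0), (5.0, 19.0), (18.0, 18.0)])
        dst = src + np.array([10.0, -4.0])
        img = rng.random((30, 30))
        warp, _ = elastic_register(img, np.zeros((30, 30)), src, dst)
        probe = rng.uniform(0, 29, size=(40, 2))
        np.testing.assert_allclose(warp(probe), probe + [10.0, -4.0], atol=1e-8)

    def test_affine_pairs_have_vanishing_radial_coefficients(self, rng):
        src = rng.uniform(0, 40, size=(8, 2))
        A = np.array([[1.2, 0.1], [-0.05, 0.9]])
        dst = src @ A.T + np.array([5.0, -2.0])
        warp, _ = elastic_register(np.zeros((40, 40)), np.zeros((40, 40)), src, dst)
        assert np.abs(warp.radial).max() < 1e-8

    def test_landmarks_interpolated_exactly(self, rng):
        src = rng.uniform(2, 38, size=(10, 2))
        dst = src + rng.normal(0, 3, size=src.shape)
        warp, _ = elastic_register(np.zeros((40, 40)), np.zeros((40, 40)), src, dst)
        assert np.abs(warp(src) - dst).max() < 1e-6

    def test_matches_scipy_thin_plate_rbf(self, rng):
        """Dual route: the in-package spline agrees with scipy's
        thin-plate-spline RBF interpolator at off-landmark points."""
        src = rng.uniform(0, 30, size=(9, 2))
        dst = src + rng.normal(0, 2.0, size=src.shape)
        warp, _ = elastic_register(np.zeros((32, 32)), np.zeros((32, 32)), src, dst)
        reference = RBFInterpolator(src, dst, kernel="thin_plate_spline", degree=1)
        probe = rng.uniform(0, 30, size=(50, 2))
        np.testing.assert_allclose(warp(probe), reference(probe), atol=1e-6)

    def test_round_trip_recovers_smooth_image(self, rng):
        yy, xx = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
        img = np.sin(xx / 8.0) + np.cos(yy / 10.0)
        src = np.array(
            [(6.0, 6.0), (40.0, 8.0), (8.0, 40.0), (40.0, 40.0), (24.0, 20.0), (20.0, 30.0)]
        )
        dst = src + rng.normal(0, 1.5, size=src.shape)
        _, fwd = elastic_register(img, img, src, dst)
        _, back = elastic_register(fwd, img, dst, src)
        inner = (slice(8, 40), slice(8, 40))
        assert np.abs(back[inner] - img[inner]).mean() < 0.05

    def test_collinear_landmarks_fall_back_to_affine(self, rng):
        src = np.array([(0.0, 0.0), (10.0, 10.0), (20.0, 20.0)])
        dst = src + np.array([1.0, 2.0])
        with pytest.warns(UserWarning, match="affine-only"):
            warp, _ = elastic_register(np.zeros((24, 24)), np.zeros((24, 24)), src, dst)
        assert warp.affine_only
        # off-line behaviour is underdetermined for collinear landmarks; the
        # fallback must still map the landmarks themselves correctly
        np.testing.assert_allclose(warp(src), dst, atol=1e-9)

    def test_color_images_warp_per_channel(self, rng):
        img = rng.random((16, 16, 3))
        pts = np.array([(2.0, 2.0), (13.0, 3.0), (3.0, 13.0), (12.0, 12.0)])
        _, warped = elastic_register(img, np.zeros((16, 16)), pts, pts)
        assert warped.shape == (16, 16, 3)
        np.testing.assert_allclose(warped[3:-3, 3:-3], img[3:-3, 3:-3], atol=1e-6)


class TestRegistrationReport:
    def test_identity_warp_reports_zero_displacement(self):
        pts = np.array([(2.0, 2.0), (13.0, 3.0), (3.0, 13.0)])
        warp, _ = elastic_register(np.zeros((16, 16)), np.zeros((16, 16)), pts, pts)
        report = registration_report(warp)
        assert report["max_residual_px"] < 1e-9
        assert report["max_displacement_px"] < 1e-6

    def test_translation_magnitude_is_uniform_sqrt116(self):
        src = np.array([(3.0, 3.0), (20.0, 4.0), (5.0, 19.0), (18.0, 18.0)])
        dst = src + np.array([10.0, -4.0])
        warp, _ = elastic_register(np.zeros((30, 30)), np.zeros((30, 30)), src, dst)
        report = registration_report(warp)
        np.testing.assert_allclose(
            report["displacement_magnitude_map"], np.sqrt(116.0), atol=1e-6
        )

    def test_residuals_vanish_for_interpolating_warp(self, rng):
        src = rng.uniform(2, 28, size=(7, 2))
        dst = src + rng.normal(0, 2, size=src.shape)
        warp, _ = elastic_register(np.zeros((30, 30)), np.zeros((30, 30)), src, dst)
        report = registration_report(warp)
        assert report["max_residual_px"] < 1e-6
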