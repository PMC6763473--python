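"""Blurred-Radon operator: geometry, assembly, adjoints, oracles."""

import math

import numpy as np
import pytest
from skimage.transform import radon

from optgauss.beams import BeamParameters, make_kernel_stamp
from optgauss.projection import (
    BeamProjector,
    ScanGeometry,
    Sinogram,
    assemble_system_matrix,
    backproject,
    beam_point,
    blur_image,
    forward_project,
)

from conftest import disk_image


class TestScanGeometry:
    def test_pitch_and_detector(self):
        g = ScanGeometry.full_turn(512, 1000.0, 400)
        assert g.pixel_pitch == pytest.approx(1000.0 / 512)
        assert g.detector_bins == 512
        assert g.n_angles == 400
        assert g.angles[0] == pytest.approx(0.9)
        assert g.angles[-1] == pytest.approx(360.0)

    def test_angle_validation(self):
        with pytest.raises(ValueError):
            ScanGeometry(64, 1000.0, np.array([10.0, 5.0]))
        with pytest.raises(ValueError):
            ScanGeometry(64, 1000.0, np.array([0.0, 180.0, 360.0]))


class TestBeamPoint:
    def test_axis_aligned_angles(self):
        assert beam_point(0.0, 3.0, 5.0) == pytest.approx((3.0, -5.0))
        assert beam_point(90.0, 3.0, 5.0) == pytest.approx((5.0, 3.0))

    def test_arclength_parametrization(self, rng):
        for alpha in rng.uniform(0, 360, size=10):
            s, z = rng.uniform(-100, 100, size=2)
            x0, y0 = beam_point(alpha, s, 0.0)
            x1, y1 = beam_point(alpha, s, z)
            assert math.hypot(x1 - x0, y1 - y0) == pytest.approx(abs(z))


class TestBlurImage:
    def test_dirac_blur_is_beam_aligned_image(self, small_geometry, dirac_stamp, rng):
        img = rng.random((64, 64))
        g = blur_image(img, 0.0, dirac_stamp, small_geometry)
        nz = dirac_stamp.n_axial
        c = 64 // 2
        # at alpha=0 the beam frame is the image frame: row = c + z/pitch
        for i in range(nz):
            row = c + i - (nz - 1) // 2
            if 0 <= row < 64:
                assert np.allclose(g[i], img[row], atol=1e-12)

    def test_constant_preserved_in_interior(self, small_geometry):
        stamp = make_kernel_stamp(BeamParameters(), small_geometry.pixel_pitch,
                                  small_geometry.diagonal + 2)
        img = np.full((64, 64), 3.5)
        g = blur_image(img, 33.0, stamp, small_geometry)
        z = stamp.z_centers
        # rows well inside the image at this angle
        inner = np.abs(z) < 150.0
        assert np.allclose(g[np.ix_(inner, np.arange(24, 40))], 3.5, rtol=1e-3)

    def test_off_focus_response_is_wider(self, small_geometry):
        p = BeamParameters()
        stamp = make_kernel_stamp(p, small_geometry.pixel_pitch,
                                  small_geometry.diagonal + 2)
        tau = stamp.tau_centers

        def second_moment(row_z_um):
            img = np.zeros((64, 64))
            c = 32
            img[c - int(round(row_z_um / small_geometry.pixel_pitch)), c] = 1.0
            g = blur_image(img, 0.0, stamp, small_geometry)
            prof = g.sum(axis=0)
            s = small_geometry.detector_offsets
            m = prof.sum()
            mu = (prof * s).sum() / m
            return (prof * (s - mu) ** 2).sum() / m

        assert second_moment(20 * p.rayleigh_range_zr) > 4 * second_moment(0.0)

    def test_shape_mismatch_rejected(self, small_geometry, dirac_stamp):
        with pytest.raises(ValueError):
            blur_image(np.zeros((32, 32)), 0.0, dirac_stamp, small_geometry)


class TestSystemAssembly:
    def test_dirac_system_matches_radon_oracle(self, small_geometry, dirac_stamp, rng):
        system = assemble_system_matrix(small_geometry, dirac_stamp)
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.exp(-((yy - 30) ** 2 + (xx - 36) ** 2) / 40.0)
        img += rng.random((64, 64))
        img *= (yy - 32) ** 2 + (xx - 32) ** 2 < 30 ** 2  # oracle needs circle support
        ours = forward_project(system, img).values
        oracle = radon(img, theta=small_geometry.angles, circle=True)
        oracle = oracle * small_geometry.pixel_pitch
        err = np.linalg.norm(ours - oracle) / np.linalg.norm(oracle)
        assert err <= 0.02

    def test_chord_lengths_of_unit_disk(self):
        geom = ScanGeometry(64, 1000.0, np.array([40.0]))
        stamp = make_kernel_stamp(BeamParameters(dirac=True), geom.pixel_pitch,
                                  geom.diagonal + 2)
        system = assemble_system_matrix(geom, stamp)
        r_px = 24
        r = r_px * geom.pixel_pitch
        img = disk_image(64, r_px)
        y = forward_project(system, img).values[:, 0]
        s = geom.detector_offsets
        inside = np.abs(s) <= 0.7 * r
        chords = 2 * np.sqrt(r ** 2 - s[inside] ** 2)
        assert np.allclose(y[inside], chords, rtol=0.03)

    def test_rows_non_negative(self, small_geometry, gbm_stamp):
        system = assemble_system_matrix(small_geometry, gbm_stamp)
        assert system.matrix.min() >= 0

    def test_adjoint_identity_exact(self, small_geometry, gbm_stamp, rng):
        system = assemble_system_matrix(small_geometry, gbm_stamp)
        x = rng.standard_normal(system.shape[1])
        y = rng.standard_normal(system.shape[0])
        lhs = system.matvec(x) @ y
        rhs = x @ system.rmatvec(y)
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)

    def test_matrix_free_adjoint_identity(self, small_geometry, gbm_stamp, rng):
        proj = BeamProjector(small_geometry, gbm_stamp)
        x = rng.standard_normal(proj.shape[1])
        y = rng.standard_normal(proj.shape[0])
        lhs = proj.matvec(x) @ y
        rhs = x @ proj.rmatvec(y)
        assert abs(lhs - rhs) <= 1e-10 * abs(lhs)

    def test_explicit_equals_matrix_free(self, small_geometry, gbm_stamp, rng):
        system = assemble_system_matrix(small_geometry, gbm_stamp)
        proj = BeamProjector(small_geometry, gbm_stamp)
        x = rng.standard_normal(proj.shape[1])
        a, b = system.matvec(x), proj.matvec(x)
        assert np.linalg.norm(a - b) <= 1e-6 * np.linalg.norm(a)

    def test_matrix_equals_blur_then_sum(self, small_geometry, gbm_stamp, rng):
        """Assembled operator equals transverse blur followed by axial sum."""
        system = assemble_system_matrix(small_geometry, gbm_stamp)
        img = rng.random((64, 64))
        y = forward_project(system, img).values
        for k, alpha in enumerate(small_geometry.angles[::7]):
            g = blur_image(img, alpha, gbm_stamp, small_geometry)
            col = g.sum(axis=0) * small_geometry.pixel_pitch
            ref = y[:, list(small_geometry.angles).index(alpha)]
            assert np.linalg.norm(col - ref) <= 1e-6 * np.linalg.norm(ref)

    def test_insufficient_stamp_extent_rejected(self, small_geometry):
        stamp = make_kernel_stamp(BeamParameters(dirac=True),
                                  small_geometry.pixel_pitch, 300.0)
        with pytest.raises(ValueError):
            assemble_system_matrix(small_geometry, stamp)

    def test_pitch_mismatch_rejected(self, small_geometry):
        stamp = make_kernel_stamp(BeamParameters(dirac=True),
                                  2 * small_geometry.pixel_pitch, 1500.0)
        with pytest.raises(ValueError):
            assemble_system_matrix(small_geometry, stamp)


class TestForwardBackward:
    def test_zero_image_zero_sinogram(self, small_geometry, dirac_stamp):
        proj = BeamProjector(small_geometry, dirac_stamp)
        assert not np.any(forward_project(proj, np.zeros((64, 64))).values)

    def test_linearity(self, small_geometry, gbm_stamp, rng):
        proj = BeamProjector(small_geometry, gbm_stamp)
        i1, i2 = rng.random((2, 64, 64))
        lhs = forward_project(proj, 2.0 * i1 - 3.0 * i2).values
        rhs = 2.0 * forward_project(proj, i1).values - 3.0 * forward_project(proj, i2).values
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_rotational_symmetry_on_lattice_angles(self, dirac_stamp):
        geom = ScanGeometry(64, 1000.0, np.array([90.0, 180.0, 270.0, 360.0]))
        proj = BeamProjector(geom, dirac_stamp)
        img = disk_image(64, 20)
        y = forward_project(proj, img).values
        for k in range(1, 4):
            assert np.allclose(y[:, k], y[:, 0], atol=1e-9)

    def test_rotational_symmetry_smooth_phantom(self, small_geometry, dirac_stamp):
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 64.0))
        proj = BeamProjector(small_geometry, dirac_stamp)
        y = forward_project(proj, img).values
        spread = np.abs(y - y[:, [0]]).max() / y.max()
        assert spread < 2e-3  # bilinear-interpolation accuracy floor

    def test_backprojection_peaks_at_source_pixel(self, small_geometry, dirac_stamp, rng):
        proj = BeamProjector(small_geometry, dirac_stamp)
        for _ in range(10):
            r, c = rng.integers(16, 48, size=2)
            e = np.zeros((64, 64))
            e[r, c] = 1.0
            bp = backproject(proj, forward_project(proj, e))
            pr, pc = np.unravel_index(np.argmax(bp), bp.shape)
            assert abs(pr - r) <= 1 and abs(pc - c) <= 1

    def test_backprojection_preserves_sign(self, small_geometry, gbm_stamp, rng):
        proj = BeamProjector(small_geometry, gbm_stamp)
        y = Sinogram(rng.random((64, 40)), small_geometry.angles,
                     small_geometry.pixel_pitch)
        assert backproject(proj, y).min() >= 0

    def test_sinogram_shape_mismatch_rejected(self, small_geometry, dirac_stamp):
        proj = BeamProjector(small_geometry, dirac_stamp)
        bad = Sinogram(np.zeros((64, 13)), np.arange(1.0, 14.0),
                       small_geometry.pixel_pitch)
        with pytest.raises(ValueError):
            backproject(proj, bad)


class TestNonCommutation:
    def test_blur_and_projection_do_not_commute(self, small_geometry):
        """Depth-dependent blur before projection differs from blurring the
        plain Radon data of an off-center point with any single profile."""
        p = BeamParameters(focal_offset_z0=150.0)
        stamp = make_kernel_stamp(p, small_geometry.pixel_pitch,
                                  small_geometry.diagonal + 152)
        img = np.zeros((64, 64))
        img[32, 45] = 1.0  # off-center point source
        blurred_then_projected = forward_project(
            BeamProjector(small_geometry, stamp), img).values

        dirac = make_kernel_stamp(BeamParameters(dirac=True),
                                  small_geometry.pixel_pitch,
                                  small_geometry.diagonal + 2)
        plain = forward_project(BeamProjector(small_geometry, dirac), img).values

        # best single-profile post-blur of the Radon data (profile at the
        # point's own radius); still cannot reproduce the angle-dependent blur
        radius = (45 - 32) * small_geometry.pixel_pitch
        prof = stamp.values[np.argmin(np.abs(stamp.z_centers - radius))]
        prof = prof / prof.sum()
        commuted = np.apply_along_axis(
            lambda col: np.convolve(col, prof, mode="same"), 0, plain)
        rel = np.linalg.norm(blurred_then_projected - commuted) / np.linalg.norm(
            blurred_then_projected)
        assert rel > 0.05
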