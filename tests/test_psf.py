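"""Vectorial dipole PSF: normalization, symmetries, convergence, astigmatic foci."""

from math import pi

import numpy as np
import pytest

from dipoleloc import (
    DipolePSFEngine,
    DipoleState,
    OpticalConfig,
    ZernikeCoefficients,
    astigmatic_foci_separation,
    bfp_field,
    image_field,
    psf_image,
)
from dipoleloc.zernike import build_wavefront, make_pupil_grid

W6 = 0.11 * 680.0


def test_config_geometry_and_validation():
    cfg = OpticalConfig()
    assert cfg.object_pixel_size_nm == pytest.approx(108.333, abs=0.01)
    with pytest.raises(ValueError):
        OpticalConfig(numerical_aperture=1.2)  # exceeds air immersion index
    with pytest.raises(ValueError):
        OpticalConfig(wavelength_nm=-5)


def test_dipole_state_validation():
    with pytest.raises(ValueError):
        DipoleState(theta=2.0)
    with pytest.raises(ValueError):
        DipoleState(x=np.nan)
    mu = DipoleState(theta=pi / 2, phi=0.0).moment
    assert mu == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)


class TestBfpField:
    def test_axial_dipole_rotationally_symmetric_and_dark_on_axis(self, cfg):
        g = make_pupil_grid(64)
        f = bfp_field(DipoleState(theta=0.0), cfg, g)
        inten = np.abs(f.ex) ** 2 + np.abs(f.ey) ** 2
        # vanishes toward the pupil center (no on-axis far field)
        center = inten[31:33, 31:33].max()
        assert center < 1e-3 * inten.max()
        # rotational symmetry: 90-degree rotation maps the grid onto itself
        assert np.allclose(inten, np.rot90(inten), atol=1e-12)

    def test_azimuth_inversion_rotates_bfp_intensity(self, cfg):
        """(theta, phi+pi) is the mirror dipole: its BFP intensity is the
        180-degree rotation of the original, not the same field."""
        g = make_pupil_grid(64)
        f1 = bfp_field(DipoleState(theta=pi / 3, phi=0.7), cfg, g)
        f2 = bfp_field(DipoleState(theta=pi / 3, phi=0.7 + pi), cfg, g)
        i1 = np.abs(f1.ex) ** 2 + np.abs(f1.ey) ** 2
        i2 = np.abs(f2.ex) ** 2 + np.abs(f2.ey) ** 2
        assert np.allclose(i2, i1[::-1, ::-1], atol=1e-12)

    def test_transverse_field(self, cfg):
        f = bfp_field(DipoleState(theta=pi / 4, phi=1.0), cfg)
        assert np.all(f.ez == 0.0)
        assert np.all(f.ex[~f.grid.mask] == 0.0)


class TestPsfImage:
    def test_normalization_to_1e12(self, sim_engine):
        for state in [(0, 0, 0, pi / 2, 0), (40, -60, 350, pi / 6, pi / 4)]:
            img = sim_engine.intensity(*state)
            assert abs(img.sum() - 1.0) < 1e-12
            assert np.all(img >= 0)

    def test_psf_image_wrapper_shape_and_units(self, cfg, astig):
        out = psf_image(DipoleState(theta=pi / 3), cfg, astig, roi_px=11, oversampling=3)
        assert out.pixels.shape == (11, 11)
        assert out.object_pixel_size_nm == pytest.approx(108.333, abs=0.01)
        with pytest.raises(ValueError):
            psf_image(DipoleState(), cfg, astig, roi_px=16)
        with pytest.raises(ValueError):
            psf_image(DipoleState(), cfg, astig, oversampling=0)

    def test_antipodal_identity_for_inplane_dipole(self, sim_engine):
        """At theta = pi/2, phi -> phi+pi negates the dipole moment, leaving
        the PSF pixelwise unchanged."""
        a = sim_engine.intensity(0, 0, 200, pi / 2, 0.7)
        b = sim_engine.intensity(0, 0, 200, pi / 2, 0.7 + pi)
        assert np.abs(a - b).max() < 1e-14

    def test_azimuth_inversion_point_reflects_tilted_psf(self, sim_engine):
        """For tilted dipoles the azimuthal antipode point-reflects the image
        (even-m astigmatism preserves the symmetry)."""
        a = sim_engine.intensity(0, 0, 200, pi / 3, 0.7)
        b = sim_engine.intensity(0, 0, 200, pi / 3, 0.7 + pi)
        assert np.abs(a - b[::-1, ::-1]).max() < 1e-14

    def test_mirror_symmetry_phi0(self, cfg, astig):
        """phi = 0 dipoles give PSFs symmetric under y -> -y, for any theta
        and defocus, with or without vertical astigmatism."""
        eng = DipolePSFEngine(cfg, astig, roi_px=17, oversampling=3)
        for theta, d in [(pi / 2, 0.0), (pi / 3, 300.0), (pi / 6, -450.0), (0.0, 150.0)]:
            img = eng.intensity(0, 0, d, theta, 0.0)
            assert np.abs(img - img[:, ::-1]).max() < 1e-14

    def test_90deg_azimuth_rotation_transposes_image(self, sim_engine):
        """theta=pi/2: rotating the dipole from phi=0 to pi/2 at d=0 with
        vertical astigmatism transposes the image (joint symmetry)."""
        a = sim_engine.intensity(0, 0, 0, pi / 2, 0.0)
        b = sim_engine.intensity(0, 0, 0, pi / 2, pi / 2)
        assert np.abs(a - b.T).max() < 1e-13

    def test_axisymmetric_patterns_at_symmetric_orientations(self, cfg, no_astig):
        """Without astigmatism at focus: theta=0 gives a rotationally
        symmetric ring; theta=pi/2 is symmetric in both mirrors."""
        eng = DipolePSFEngine(cfg, no_astig, roi_px=17, oversampling=3)
        ring = eng.intensity(0, 0, 0, 0.0, 0.0)
        assert np.abs(ring - ring.T).max() < 1e-13
        assert np.abs(ring - ring[::-1, :]).max() < 1e-13
        # ring-like: center pixel is not the maximum
        assert ring[8, 8] < ring.max()
        inplane = eng.intensity(0, 0, 0, pi / 2, 0.0)
        assert np.abs(inplane - inplane[::-1, :]).max() < 1e-13
        assert np.abs(inplane - inplane[:, ::-1]).max() < 1e-13

    def test_pupil_sampling_convergence(self, cfg, astig):
        """Doubling pupil sampling 64 -> 128 moves no normalized pixel by
        more than 1e-4."""
        e64 = DipolePSFEngine(cfg, astig, oversampling=3, pupil_samples=64)
        e128 = DipolePSFEngine(cfg, astig, oversampling=3, pupil_samples=128)
        for state in [(0, 0, 0, pi / 2, 0), (30, -40, 200, pi / 3, pi / 4),
                      (50, 20, -400, pi / 6, 0)]:
            assert np.abs(e64.intensity(*state) - e128.intensity(*state)).max() < 1e-4

    def test_oversampling_convergence_toward_9(self, cfg, astig):
        """Max-pixel discretization error shrinks as oversampling rises."""
        ref = DipolePSFEngine(cfg, astig, oversampling=15).intensity(30, 20, 250, pi / 3, pi / 4)
        errs = []
        for os in (1, 3, 9):
            img = DipolePSFEngine(cfg, astig, oversampling=os).intensity(30, 20, 250, pi / 3, pi / 4)
            errs.append(np.abs(img - ref).max())
        assert errs[0] > errs[1] > errs[2]

    def test_emitter_shift_matches_pixel_shift(self, cfg, astig):
        """Moving the emitter one full pixel shifts the image one pixel
        (Fourier shift theorem, interior pixels)."""
        eng = DipolePSFEngine(cfg, astig, roi_px=17, oversampling=3)
        a = eng.intensity(0, 0, 100, pi / 3, pi / 4)
        b = eng.intensity(cfg.object_pixel_size_nm, 0, 100, pi / 3, pi / 4)
        shifted = np.roll(a, 1, axis=0)
        assert np.abs(shifted[2:, :] - b[2:, :]).max() < 5e-5


class TestImageField:
    def test_piston_leaves_normalized_intensity_unchanged(self, cfg):
        g = make_pupil_grid(64)
        pupil = bfp_field(DipoleState(theta=pi / 3, phi=0.5), cfg, g)
        pts = np.array([[0.0, 0.0], [50.0, -30.0], [200.0, 100.0]])
        w0 = np.zeros_like(g.uu)
        w_piston = build_wavefront(ZernikeCoefficients({1: 123.0}), g)
        e0 = image_field(pupil, w0, cfg, pts)
        e1 = image_field(pupil, w_piston, cfg, pts)
        i0 = np.sum(np.abs(e0) ** 2, axis=1)
        i1 = np.sum(np.abs(e1) ** 2, axis=1)
        assert np.allclose(i1 / i1[0], i0 / i0[0], rtol=1e-12)

    def test_fourier_shift_theorem_pointwise(self, cfg):
        """Field of a shifted emitter at (x_f + delta, y_f) equals the
        unshifted field at (x_f, y_f); shifting the evaluation grid is
        equivalent to tilting the pupil."""
        g = make_pupil_grid(64)
        pupil = bfp_field(DipoleState(theta=pi / 2, phi=0.3), cfg, g)
        w0 = np.zeros_like(g.uu)
        delta = 77.0
        pts = np.array([[10.0, 20.0]])
        pts_shifted = pts + np.array([[delta, 0.0]])
        e_ref = image_field(pupil, w0, cfg, pts)
        # emitter displacement as a pupil tilt phase
        a = 2 * pi * cfg.numerical_aperture / cfg.wavelength_nm
        tilt = np.exp(1j * a * delta * g.uu)
        from dipoleloc.psf import PupilField

        pupil_t = PupilField(ex=pupil.ex * tilt, ey=pupil.ey * tilt,
                             ez=pupil.ez, grid=g)
        e_shift = image_field(pupil_t, w0, cfg, pts_shifted)
        assert np.allclose(e_shift[:, :2], e_ref[:, :2], rtol=1e-10, atol=1e-14)

    def test_input_validation(self, cfg):
        g = make_pupil_grid(64)
        pupil = bfp_field(DipoleState(), cfg, g)
        with pytest.raises(ValueError):
            image_field(pupil, np.zeros_like(g.uu), cfg, np.empty((0, 2)))
        with pytest.raises(ValueError):
            image_field(pupil, np.zeros((10, 10)), cfg, np.array([[0.0, 0.0]]))


class TestAstigmaticFoci:
    def test_zero_astigmatism_zero_separation(self, cfg, no_astig):
        assert astigmatic_foci_separation(cfg, no_astig) == 0.0

    def test_study_astigmatism_separation_near_1p4um(self, cfg, astig):
        """w6 = 0.11 lambda at NA 0.7 separates the line foci by ~1.4 um."""
        sep = astigmatic_foci_separation(cfg, astig)
        assert sep == pytest.approx(1400.0, rel=0.15)

    def test_separation_linear_in_w6(self, cfg, astig):
        sep1 = astigmatic_foci_separation(cfg, astig)
        sep2 = astigmatic_foci_separation(
            cfg, ZernikeCoefficients({6: 2 * W6}), d_max_nm=3000.0, d_step_nm=20.0
        )
        assert sep2 / sep1 == pytest.approx(2.0, rel=0.05)

    def test_scan_edge_raises(self, cfg, astig):
        with pytest.raises(RuntimeError, match="widen"):
            astigmatic_foci_separation(cfg, astig, d_max_nm=400.0)
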