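"""MTF estimation validated against closed-form Gaussian transfer functions.

For a Gaussian PSF of width sigma the MTF is exp(-2 pi^2 sigma^2 f^2), so
the cutoff at modulation level L sits at sqrt(ln(1/L) / (2 pi^2 sigma^2)).
All cube volumes here sample the *exact* continuously blurred cube (erf
closed form), so the only error under test is the estimator's own.
"""

import numpy as np
import pytest

import lungqct as lq

SPACING = (0.51, 0.51, 0.51)


def gaussian_cutoff(sigma: float, level: float) -> float:
    """Analytic cutoff frequency in cycles/cm for a Gaussian PSF."""
    return np.sqrt(np.log(1.0 / level) / (2.0 * np.pi ** 2 * sigma ** 2)) * 10.0


def make_cube(sigma, shape=(110, 110, 110), center=(0.13, -0.21, 0.07),
              noise_sd=0.0, seed=0, tilt=(3.0, 3.0)):
    vol = lq.analytic_cube_volume(shape, SPACING, center, sigma=sigma,
                                  tilt_deg=tilt)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = lq.VoxelVolume(vol.voxels + rng.normal(0, noise_sd, vol.shape),
                             spacing=vol.spacing, origin=vol.origin)
    return vol


def cube_mask(vol):
    return lq.ROIMask("mtf_cube", vol.voxels > -535.0)


class TestLocateCube:
    def test_center_and_half_edge_recovery(self):
        vol = make_cube(0.5, center=(1.3, -0.7, 0.4))
        pose = lq.locate_cube(vol, cube_mask(vol))
        assert np.allclose(pose.center, (1.3, -0.7, 0.4), atol=0.3)
        assert pose.half_edge == pytest.approx(10.0, abs=0.3)
        assert len(pose.exposed_faces) == 6  # free-standing cube: no cap

    def test_translation_invariant_half_edge(self):
        a = lq.locate_cube(*(lambda v: (v, cube_mask(v)))(make_cube(0.5)))
        moved = make_cube(0.5, center=(3.57, 2.04, -1.53))
        b = lq.locate_cube(moved, cube_mask(moved))
        assert b.half_edge == pytest.approx(a.half_edge, abs=0.05)

    def test_elongated_region_rejected(self):
        vox = np.full((80, 80, 80), -1000.0)
        vox[20:60, 35:45, 35:45] = -70.0  # 2:1 aspect box
        vol = lq.VoxelVolume(vox, spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="not cube-like"):
            lq.locate_cube(vol, cube_mask(vol))


class TestExtractESF:
    def test_matches_erf_profile(self):
        """Noiseless averaged ESF equals the Gaussian edge (erf) profile to
        better than 1% of the edge height."""
        sigma = 0.5
        vol = make_cube(sigma)
        pose = lq.locate_cube(vol, cube_mask(vol))
        profile = lq.extract_esf(vol, pose, (0, +1))
        from scipy.special import erf
        x = profile.distances
        expected = -1000.0 + 930.0 * 0.5 * (1 - erf(x / (sigma * np.sqrt(2))))
        dev = np.max(np.abs(profile.esf_values - expected)) / 930.0
        assert dev < 0.01

    def test_single_ray_close_to_many_rays_noiseless(self):
        vol = make_cube(0.5)
        pose = lq.locate_cube(vol, cube_mask(vol))
        p1 = lq.extract_esf(vol, pose, (1, +1), ray_count=1)
        p64 = lq.extract_esf(vol, pose, (1, +1), ray_count=64)
        common = np.abs(p1.distances) < 6.0
        dev = np.max(np.abs(p1.esf_values[common]
                            - np.interp(p1.distances[common], p64.distances,
                                        p64.esf_values))) / 930.0
        # a single ray only has native-pitch samples; the fine grid between
        # them is linearly interpolated, which bounds the agreement
        assert dev < 0.05

    def test_plateau_levels_are_material_hu(self):
        vol = make_cube(0.4)
        pose = lq.locate_cube(vol, cube_mask(vol))
        p = lq.extract_esf(vol, pose, (2, +1))
        assert p.esf_values[:5].mean() == pytest.approx(-70.0, abs=5.0)
        assert p.esf_values[-5:].mean() == pytest.approx(-1000.0, abs=5.0)

    def test_unexposed_face_rejected(self):
        vol = make_cube(0.5)
        pose = lq.locate_cube(vol, cube_mask(vol))
        pose.exposed_faces.remove((2, -1))
        with pytest.raises(ValueError, match="not exposed"):
            lq.extract_esf(vol, pose, (2, -1))


class TestESFToMTF:
    def test_curve_matches_gaussian_transfer_function(self):
        sigma = 0.5
        vol = make_cube(sigma)
        pose = lq.locate_cube(vol, cube_mask(vol))
        curve = lq.esf_to_mtf(lq.extract_esf(vol, pose, (0, +1)))
        f_mm = curve.frequencies / 10.0
        expected = np.exp(-2 * np.pi ** 2 * sigma ** 2 * f_mm ** 2)
        upto = curve.frequencies <= gaussian_cutoff(sigma, 0.2)
        assert np.max(np.abs(curve.modulation[upto] - expected[upto])) < 0.02

    def test_zero_frequency_normalization(self):
        vol = make_cube(0.8)
        pose = lq.locate_cube(vol, cube_mask(vol))
        curve = lq.esf_to_mtf(lq.extract_esf(vol, pose, (1, +1)))
        assert curve.modulation[0] == 1.0
        assert curve.frequencies[0] == 0.0

    def test_window_changes_noiseless_f50_below_1pct(self):
        """The Hann taper is nearly transparent for a well-contained LSF."""
        vol = make_cube(0.5)
        pose = lq.locate_cube(vol, cube_mask(vol))
        profile = lq.extract_esf(vol, pose, (0, +1))
        windowed = lq.esf_to_mtf(profile)
        # reference: same pipeline without the window
        lsf = np.gradient(profile.esf_values, profile.pitch)
        raw = np.abs(np.fft.rfft(lsf))
        raw_curve = lq.MTFCurve.from_samples(
            "x", np.fft.rfftfreq(len(lsf), d=profile.pitch) * 10, raw / raw[0])
        assert windowed.f50 == pytest.approx(raw_curve.f50, rel=0.01)


class TestCutoffs:
    def test_closed_form_cutoffs_sigma_05(self):
        vol = make_cube(0.5)
        pose = lq.locate_cube(vol, cube_mask(vol))
        inplane, zc = lq.inplane_and_z_mtf(vol, pose, reach_limit=17.0)
        assert inplane.f50 == pytest.approx(3.748, rel=0.02)
        assert inplane.f20 == pytest.approx(5.711, rel=0.02)
        assert zc.f50 == pytest.approx(3.748, rel=0.02)

    def test_level_one_is_zero_frequency(self):
        vol = make_cube(0.5)
        pose = lq.locate_cube(vol, cube_mask(vol))
        curve = lq.esf_to_mtf(lq.extract_esf(vol, pose, (0, +1)))
        assert lq.mtf_cutoff(curve, 1.0) == 0.0

    def test_uncrossed_level_rejected_with_band_limit(self):
        curve = lq.MTFCurve("x", np.linspace(0, 5, 20),
                            np.linspace(1, 0.6, 20), f50=np.nan, f20=np.nan)
        with pytest.raises(ValueError, match="5.00 cycles/cm"):
            lq.mtf_cutoff(curve, 0.5)


class TestInplaneAndZ:
    def test_isotropic_psf_symmetric_cutoffs(self):
        vol = make_cube(0.8)
        pose = lq.locate_cube(vol, cube_mask(vol))
        inplane, zc = lq.inplane_and_z_mtf(vol, pose, reach_limit=17.0)
        assert zc.f50 == pytest.approx(inplane.f50, rel=0.02)

    def test_anisotropic_psf_orders_cutoffs(self):
        """A wider z PSF must push the z cutoff below the in-plane one."""
        vol = lq.analytic_cube_volume((110, 110, 110), SPACING,
                                      (0.13, -0.21, 0.07),
                                      sigma=(0.5, 0.5, 0.9), tilt_deg=(0, 0))
        pose = lq.locate_cube(vol, cube_mask(vol))
        inplane, zc = lq.inplane_and_z_mtf(vol, pose, reach_limit=17.0)
        assert zc.f50 < inplane.f50
        assert zc.f20 < inplane.f20

    def test_f20_exceeds_f50(self):
        for sigma in (0.4, 0.9):
            vol = make_cube(sigma)
            pose = lq.locate_cube(vol, cube_mask(vol))
            inplane, zc = lq.inplane_and_z_mtf(vol, pose, reach_limit=17.0)
            assert inplane.f20 > inplane.f50
            assert zc.f20 > zc.f50
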