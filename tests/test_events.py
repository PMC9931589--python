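import math

import numpy as np
import pytest
from scipy import stats

from selfdenoise3d import (
    EventTruth,
    FWHM_PER_SIGMA,
    SystemPSF,
    bin_events,
    event_geometry,
    extract_profiles,
    fit_gaussian,
    fwhm,
    make_event_fixture,
    rl_deconvolve,
)
from selfdenoise3d.events import FitError


class TestExtractProfiles:
    def _volume(self):
        psf = SystemPSF(lateral_fwhm_um=2.0, axial_fwhm_um=3.0)
        truth = EventTruth(center=(24, 24, 12, 4), fwhm_px=(8, 8, 8), amplitude=5.0)
        return make_event_fixture([truth], psf, shape=(48, 48, 24, 8)), truth

    def test_profiles_peak_at_center(self):
        vol, truth = self._volume()
        profiles = extract_profiles(vol, truth.center, half_width=10, half_width_z=6)
        for axis in ("x", "y", "z"):
            assert np.argmax(profiles[axis]) == len(profiles[axis]) // 2

    def test_profile_length(self):
        vol, truth = self._volume()
        profiles = extract_profiles(vol, truth.center, half_width=7)
        assert len(profiles["x"]) == 15

    def test_edge_event_excluded(self):
        vol, _ = self._volume()
        with pytest.raises(ValueError, match="edge"):
            extract_profiles(vol, (2, 24, 12, 4), half_width=10)


class TestFitGaussian:
    def test_noiseless_parameters_recovered_to_four_decimals(self):
        x = np.arange(-10.0, 11.0)
        profile = 10.0 * np.exp(-0.5 * (x / 2.0) ** 2) + 1.0
        fit = fit_gaussian(profile, coords=x)
        assert fit.amplitude == pytest.approx(10.0, abs=1e-4)
        assert fit.center == pytest.approx(0.0, abs=1e-4)
        assert fit.sigma == pytest.approx(2.0, abs=1e-4)
        assert fit.baseline == pytest.approx(1.0, abs=1e-4)

    def test_constant_profile_flagged(self):
        with pytest.raises(FitError):
            fit_gaussian(np.ones(11))

    def test_origin_shift_equivariance(self):
        x = np.arange(21.0)
        profile = 4.0 * np.exp(-0.5 * ((x - 10.0) / 1.5) ** 2) + 0.2
        f0 = fit_gaussian(profile, coords=x)
        f1 = fit_gaussian(profile, coords=x + 100.0)
        assert f1.center - f0.center == pytest.approx(100.0, abs=1e-6)
        assert f1.sigma == pytest.approx(f0.sigma, abs=1e-8)


class TestRichardsonLucy:
    def test_delta_psf_leaves_curve_unchanged(self):
        curve = np.exp(-0.5 * ((np.arange(64) - 32) / 4.0) ** 2)
        psf = np.zeros(9)
        psf[4] = 1.0
        out = rl_deconvolve(curve, psf, iterations=25)
        np.testing.assert_allclose(out, curve, atol=1e-8)

    def test_gaussian_deconvolution_approaches_analytic_width(self):
        # sigma_obs = 2 px by sigma_psf = 1 px -> sigma_true = sqrt(3);
        # FWHM -> 2.3548 * sqrt(3), within 2% at 200 iterations
        step = 0.1
        grid = np.arange(-15.0, 15.0 + step, step)
        observed = np.exp(-0.5 * (grid / 2.0) ** 2)
        psf = np.exp(-0.5 * (grid / 1.0) ** 2)
        psf /= psf.sum()
        out = rl_deconvolve(observed, psf, iterations=200)
        width = fwhm(out, coords=grid, baseline=0.0)
        assert width == pytest.approx(FWHM_PER_SIGMA * math.sqrt(3.0), rel=0.02)

    def test_mass_conserved_under_circular_boundary(self):
        rng = np.random.default_rng(0)
        curve = rng.uniform(0.5, 2.0, 128)
        psf = np.exp(-0.5 * (np.arange(-5, 6) / 1.5) ** 2)
        psf /= psf.sum()
        out = rl_deconvolve(curve, psf, iterations=50)
        assert out.sum() == pytest.approx(curve.sum(), rel=1e-6)

    def test_zero_psf_rejected(self):
        with pytest.raises(ValueError, match="positive mass"):
            rl_deconvolve(np.ones(8), np.zeros(3))


class TestFwhm:
    def test_analytic_gaussian_width(self):
        x = np.arange(-20.0, 20.0, 0.01)  # dense sampling: interpolation error -> 0
        curve = np.exp(-0.5 * x**2)
        assert fwhm(curve, coords=x) == pytest.approx(FWHM_PER_SIGMA, abs=5e-3)

    def test_dense_sampling_sigma_two(self):
        x = np.arange(-20.0, 20.0, 0.1)
        curve = np.exp(-0.5 * (x / 2.0) ** 2)
        assert fwhm(curve, coords=x) == pytest.approx(2 * FWHM_PER_SIGMA, abs=0.01)

    def test_amplitude_scaling_leaves_width_unchanged(self):
        x = np.arange(-15.0, 16.0)
        curve = np.exp(-0.5 * (x / 3.0) ** 2)
        assert fwhm(5 * curve, coords=x) == pytest.approx(fwhm(curve, coords=x))

    def test_no_crossing_flagged(self):
        with pytest.raises(FitError):
            fwhm(np.ones(7))


class TestEventGeometry:
    PSF = SystemPSF(lateral_fwhm_um=2.0, axial_fwhm_um=3.0)

    def _recover(self, fwhm_px, noise=0.0):
        truth = EventTruth(center=(24, 24, 12, 4), fwhm_px=fwhm_px, amplitude=5.0)
        vol = make_event_fixture([truth], self.PSF, shape=(48, 48, 24, 8),
                                 noise_sigma=noise, seed=1)
        profiles = extract_profiles(vol, truth.center, half_width=14, half_width_z=9)
        return event_geometry(profiles, self.PSF, pixel_size_um=1.0,
                              z_spacing_um=1.0, rl_iterations=200)

    def test_isotropic_event_has_near_zero_ellipticity(self):
        ev = self._recover((9.0, 9.0, 9.0))
        for plane in ("xy", "yz", "xz"):
            assert ev.ellipticities[plane] < 0.05

    def test_two_to_one_axis_ratio_gives_half_ellipticity(self):
        # diameters a = 2b in the x-y plane -> ellipticity (a-b)/a = 0.5
        ev = self._recover((12.0, 6.0, 8.0))
        assert ev.ellipticities["xy"] == pytest.approx(0.5, abs=0.05)

    def test_anisotropic_diameters_recovered_within_five_percent(self):
        truth_fwhm = {"x": 12.0, "y": 10.0, "z": 8.0}
        ev = self._recover((12.0, 10.0, 8.0), noise=0.02)
        assert not ev.flags
        for axis, expected in truth_fwhm.items():
            assert ev.diameters_um[axis] == pytest.approx(expected, rel=0.05)


class TestBinEvents:
    def test_counts_sum_to_event_count(self, rng):
        times = rng.uniform(0, 3600, 196)
        counts = bin_events(times, 120.0, 3600.0)
        assert counts.sum() == 196
        assert len(counts) == 30

    def test_boundary_goes_to_later_bin(self):
        counts = bin_events(np.array([120.0]), 120.0, 3600.0)
        assert counts[0] == 0 and counts[1] == 1

    def test_uniform_times_chi_square_consistent(self):
        rng = np.random.default_rng(42)
        times = rng.uniform(0, 3600, 3000)
        counts = bin_events(times, 120.0, 3600.0)
        stat, p = stats.chisquare(counts)
        assert p > 0.01

    def test_out_of_session_rejected(self):
        with pytest.raises(ValueError):
            bin_events(np.array([3600.0]), 120.0, 3600.0)
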