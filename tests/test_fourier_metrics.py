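import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catphanqa import fourier_metrics as fm
from catphanqa.errors import MetricError
from catphanqa.scan_io import ScanVolume


def _analytic_hwhm(sigma):
    """f where exp(-2 pi^2 sigma^2 f^2) = 1/2."""
    return math.sqrt(math.log(2.0) / (2.0 * math.pi ** 2 * sigma ** 2))


class TestPsfFit:
    def test_sigma_recovered_on_synthetic_scan(self, std_scan, std_landmarks):
        volume, truth = std_scan
        fit = fm.fit_psf(volume, std_landmarks.source)
        h = volume.pixel_spacing[0]
        effective = math.sqrt(truth.psf_sigma ** 2 + h ** 2 / 12.0)
        assert fit.radial_sigma == pytest.approx(effective, rel=0.05)

    def test_isotropic_source(self, std_scan, std_landmarks):
        volume, _ = std_scan
        fit = fm.fit_psf(volume, std_landmarks.source)
        assert fit.sigma_x == pytest.approx(fit.sigma_y, rel=0.10)

    def test_center_recovered(self, std_scan, std_landmarks):
        volume, truth = std_scan
        fit = fm.fit_psf(volume, std_landmarks.source)
        assert fit.center_x == pytest.approx(truth.source_xy_mm[0], abs=0.1)
        assert fit.center_y == pytest.approx(truth.source_xy_mm[1], abs=0.1)

    def test_radial_psf_peak(self):
        fit = fm.PsfFit(0.5, 0.5, 0.0, 0.0, 100.0, 100.0)
        assert fit.radial_psf(np.array([0.0]))[0] == pytest.approx(100.0)


class TestMtfFromPsf:
    @pytest.mark.parametrize("sigma", [0.3, 0.6, 1.0])
    def test_analytic_matches_closed_form(self, sigma):
        fit = fm.PsfFit(sigma, sigma, 0.0, 0.0, 50.0, 50.0)
        curve, hwhm, _ = fm.mtf_from_psf(fit, method="analytic")
        expected = np.exp(-2.0 * math.pi ** 2 * sigma ** 2
                          * curve.frequencies ** 2)
        np.testing.assert_allclose(curve.values, expected, atol=1e-12)
        assert hwhm == pytest.approx(_analytic_hwhm(sigma), rel=0.01)

    @pytest.mark.parametrize("sigma", [0.3, 0.6, 1.0])
    def test_quadrature_matches_closed_form(self, sigma):
        fit = fm.PsfFit(sigma, sigma, 0.0, 0.0, 50.0, 50.0)
        curve, hwhm, _ = fm.mtf_from_psf(fit, method="quadrature")
        expected = np.exp(-2.0 * math.pi ** 2 * sigma ** 2
                          * curve.frequencies ** 2)
        assert np.max(np.abs(curve.values - expected)) < 1e-4
        assert hwhm == pytest.approx(_analytic_hwhm(sigma), rel=0.01)

    def test_normalised_at_zero(self):
        fit = fm.PsfFit(0.6, 0.7, 0.0, 0.0, 80.0, 90.0)
        curve, _, _ = fm.mtf_from_psf(fit)
        assert curve.values[0] == 1.0
        assert np.all(np.diff(curve.values) <= 1e-12)  # monotone decreasing

    def test_hwtm_crossing(self):
        fit = fm.PsfFit(0.5, 0.5, 0.0, 0.0, 1.0, 1.0)
        curve, hwhm, hwtm = fm.mtf_from_psf(fit)
        expected_hwtm = math.sqrt(math.log(10.0)
                                  / (2.0 * math.pi ** 2 * 0.25))
        assert hwtm == pytest.approx(expected_hwtm, rel=0.01)
        assert hwtm > hwhm

    def test_unknown_method_rejected(self):
        fit = fm.PsfFit(0.5, 0.5, 0.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="method"):
            fm.mtf_from_psf(fit, method="nope")

    @given(sigma=st.floats(0.25, 1.5))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_hwhm_inverse_in_sigma(self, sigma):
        fit = fm.PsfFit(sigma, sigma, 0.0, 0.0, 1.0, 1.0)
        _, hwhm, _ = fm.mtf_from_psf(fit)
        assert hwhm * sigma == pytest.approx(
            math.sqrt(math.log(2.0)) / (math.pi * math.sqrt(2.0)), rel=0.01)


class TestEdgeMtf:
    def _edge_image(self, sigma, pixel_size=0.5, n=160, tilt_deg=3.0):
        """Pixel-sampled blurred edge (error-function profile), tilted."""
        from scipy.special import erf
        x = (np.arange(n) - (n - 1) / 2.0) * pixel_size
        y = ((n - 1) / 2.0 - np.arange(n)) * pixel_size
        a = math.radians(tilt_deg)
        d = x[None, :] * math.cos(a) - y[:, None] * math.sin(a)
        return 0.5 * (1.0 + erf(d / (sigma * math.sqrt(2.0)))) * 100.0

    def test_matches_gaussian_mtf(self):
        sigma = 0.6
        img = self._edge_image(sigma)
        curve = fm.mtf_from_oversampled_edge(img, 3.0, 0.5)
        expected = np.exp(-2.0 * math.pi ** 2 * sigma ** 2
                          * curve.frequencies ** 2)
        sel = expected >= 0.1
        assert np.max(np.abs(curve.values[sel] - expected[sel])) < 0.03

    def test_small_tilt_rejected(self):
        img = self._edge_image(0.6, tilt_deg=0.2)
        with pytest.raises(MetricError, match="tilt"):
            fm.mtf_from_oversampled_edge(img, 0.2, 0.5)


def _white_noise_volume(sigma, seed, n=256, px=0.9, slices=16, thickness=3.0):
    rng = np.random.default_rng(seed)
    hu = rng.normal(0.0, sigma, size=(slices, n, n))
    return ScanVolume(hu, (px, px), np.arange(slices) * thickness, thickness)


class TestNps:
    def test_white_noise_flat_spectrum(self):
        volume = _white_noise_volume(10.0, 5)
        nps2d = fm.nps_2d(volume, 4)
        # white noise in the difference image: NPS approx 2 sigma^2 dx dy / 2
        expected = 10.0 ** 2 * 0.9 * 0.9
        assert nps2d.nps.mean() == pytest.approx(expected, rel=0.05)

    def test_roi_count_near_target(self):
        volume = _white_noise_volume(10.0, 5)
        nps2d = fm.nps_2d(volume, 4)
        assert 150 <= nps2d.n_roi <= 260

    def test_scalar_recovers_pixel_noise(self):
        volume = _white_noise_volume(10.0, 6)
        curve = fm.nps_radial(fm.nps_2d(volume, 4))
        assert fm.nps_scalar(curve) == pytest.approx(10.0, rel=0.05)

    def test_identical_slices_zero(self):
        """spacing_factor 0 differences a slice with itself: NPS identically 0."""
        volume = _white_noise_volume(10.0, 7)
        nps2d = fm.nps_2d(volume, 4, spacing_factor=0.0)
        assert np.all(nps2d.nps == 0.0)
        assert fm.nps_scalar(fm.nps_radial(nps2d)) == 0.0

    def test_partner_slice_out_of_range(self):
        volume = _white_noise_volume(10.0, 8, slices=6)
        with pytest.raises(MetricError, match="partner slice"):
            fm.nps_2d(volume, 4)

    def test_correlated_noise_not_flat(self):
        from catphanqa.simulate import SimulationConfig, render_scan
        from conftest import FAST_KWARGS
        volume, truth = render_scan(SimulationConfig(
            **{**FAST_KWARGS, "noise_sigma": 10.0, "noise_correlation": 1.2,
               "rng_seed": 9}))
        k = truth.module_center_slices["ctp486"]
        curve = fm.nps_radial(fm.nps_2d(volume, k,
                                        center_mm=truth.phantom_center_mm))
        # low-pass shaping: high-frequency NPS well below low-frequency NPS
        n = len(curve.values)
        low = curve.values[1:n // 6].mean()
        high = curve.values[n // 2:2 * n // 3].mean()
        assert high < 0.25 * low
        # and the scalar still integrates to the configured pixel noise
        assert fm.nps_scalar(curve) == pytest.approx(10.0, rel=0.10)

    def test_radial_curve_structure(self):
        volume = _white_noise_volume(5.0, 10)
        curve = fm.nps_radial(fm.nps_2d(volume, 4))
        assert curve.frequencies[0] == 0.0
        assert curve.bin_weights is not None
        # total measure equals the full frequency-plane area 1/(dx dy)
        assert curve.bin_weights.sum() == pytest.approx(1.0 / (0.9 * 0.9))

    def test_negative_values_rejected(self):
        curve = fm.SpectralCurve(np.array([0.0, 0.1, 0.2]),
                                 np.array([1.0, -0.5, 0.2]), 0.1)
        with pytest.raises(MetricError, match="negative"):
            fm.nps_scalar(curve)
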