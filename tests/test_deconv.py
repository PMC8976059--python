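import numpy as np
import pytest

from llpsnmr.deconv import (
    DeconvolutionResult,
    LorentzianPeak,
    NoPeakError,
    assign_phases,
    fit_lorentzians,
    initial_guess,
    lorentzian_profile,
    monte_carlo_ci,
    select_n_components,
)
from tests.conftest import make_spectrum

TWO_PEAKS = [(-77.30, 15.0, 0.6), (-77.05, 80.0, 0.4)]


class TestLorentzianProfile:
    def test_peak_height_closed_form(self):
        # area 1, gamma = 1 ppm (fwhm = 2*freq Hz) -> height 1/pi at the centre
        y = lorentzian_profile(np.array([-77.0]), -77.0, 2 * 470.0, 1.0, 470.0)
        assert y[0] == pytest.approx(1 / np.pi, rel=1e-12)

    def test_symmetry(self):
        d = np.linspace(0.01, 2, 50)
        left = lorentzian_profile(-77.0 - d, -77.0, 30.0, 1.0)
        right = lorentzian_profile(-77.0 + d, -77.0, 30.0, 1.0)
        np.testing.assert_allclose(left, right, rtol=1e-14)

    def test_trapezoid_integral_recovers_area(self):
        # closed-form truncated integral: int over +/-k*gamma = (2/pi) atan(k) * area,
        # so +/-500 gamma captures all but ~0.13% of the area
        gamma_ppm = 20.0 / (2 * 470.0)
        x = np.linspace(-77 - 500 * gamma_ppm, -77 + 500 * gamma_ppm, 200001)
        integral = np.trapezoid(lorentzian_profile(x, -77.0, 20.0, 0.7), x)
        expected = (2 / np.pi) * np.arctan(500.0) * 0.7
        assert integral == pytest.approx(expected, rel=1e-5)
        assert integral == pytest.approx(0.7, rel=2e-3)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            lorentzian_profile(np.array([0.0]), 0.0, 0.0, 1.0)


class TestInitialGuess:
    def test_single_peak_seed_near_truth(self):
        spec = make_spectrum([(-77.2, 20.0, 1.0)])
        (c, w, a), = initial_guess(spec, 1)
        assert abs(c - (-77.2)) <= spec.step_ppm

    def test_two_separated_peaks_both_found(self):
        spec = make_spectrum([(-77.5, 20.0, 1.0), (-76.5, 20.0, 0.8)])
        seeds = initial_guess(spec, 2)
        centers = sorted(s[0] for s in seeds)
        assert abs(centers[0] - (-77.5)) <= 2 * spec.step_ppm
        assert abs(centers[1] - (-76.5)) <= 2 * spec.step_ppm

    def test_flat_spectrum_raises(self):
        spec = make_spectrum([], sigma=0.0)
        spec.intensity[:] = 0.0
        with pytest.raises(NoPeakError):
            initial_guess(spec, 1)


class TestFitLorentzians:
    def test_noiseless_single_recovery(self):
        spec = make_spectrum([(-77.0, 20.0, 1.0)])
        fit = fit_lorentzians(spec, 1)
        p = fit.peaks[0]
        assert fit.converged
        assert p.center == pytest.approx(-77.0, abs=1e-6)
        assert p.fwhm == pytest.approx(20.0, rel=1e-6)
        assert p.area == pytest.approx(1.0, rel=1e-6)

    def test_noiseless_two_component_recovery(self):
        spec = make_spectrum(TWO_PEAKS)
        fit = fit_lorentzians(spec, 2)
        got = sorted([(p.center, p.fwhm, p.area) for p in fit.peaks])
        for (gc, gw, ga), (tc, tw, ta) in zip(got, sorted(TWO_PEAKS)):
            assert gc == pytest.approx(tc, abs=1e-4 * abs(tc))
            assert gw == pytest.approx(tw, rel=1e-4)
            assert ga == pytest.approx(ta, rel=1e-4)

    def test_noisy_replicate_recovery(self):
        # SNR 100 on the tallest peak; subset of the full acceptance sweep
        height = max(2 * a / (np.pi * w / 470.0) for _, w, a in TWO_PEAKS)
        errs_c, errs_a = [], []
        for seed in range(10):
            spec = make_spectrum(TWO_PEAKS, sigma=height / 100, seed=seed)
            fit = fit_lorentzians(spec, 2)
            got = sorted([(p.center, p.area) for p in fit.peaks])
            for (gc, ga), (tc, _, ta) in zip(got, sorted(TWO_PEAKS)):
                errs_c.append(abs(gc - tc))
                errs_a.append(abs(ga - ta) / ta)
        assert max(errs_c) < 0.005
        assert max(errs_a) < 0.03

    def test_area_closure_noiseless(self):
        spec = make_spectrum(TWO_PEAKS, lo=-79.5, hi=-74.5, n=8192)
        fit = fit_lorentzians(spec, 2)
        integral = np.trapezoid(spec.intensity, spec.axis_ppm)
        # finite window clips Lorentzian wings; closure still holds to 2%
        assert fit.total_area() == pytest.approx(integral, rel=0.02)

    def test_seed_outside_axis_rejected(self):
        spec = make_spectrum([(-77.0, 20.0, 1.0)])
        with pytest.raises(ValueError, match="outside"):
            fit_lorentzians(spec, 1, [(-90.0, 20.0, 1.0)])


class TestSelectNComponents:
    def test_single_peak_with_noise(self):
        spec = make_spectrum([(-77.0, 25.0, 1.0)], sigma=0.05, seed=1)
        assert select_n_components(spec) == 1

    def test_two_resolved_peaks(self):
        spec = make_spectrum([(-77.5, 20.0, 0.6), (-76.5, 40.0, 0.4)], sigma=0.01, seed=2)
        assert select_n_components(spec) == 2

    def test_coincident_identical_peaks_merge(self):
        spec = make_spectrum([(-77.0, 30.0, 0.5), (-77.0, 30.0, 0.5)], sigma=0.01, seed=3)
        assert select_n_components(spec) == 1


class TestMonteCarloCI:
    def test_noiseless_cis_collapse(self):
        spec = make_spectrum([(-77.0, 20.0, 1.0)])
        fit = fit_lorentzians(spec, 1)
        out = monte_carlo_ci(spec, fit, n_reps=50, seed=0)
        lo, hi = out.peaks[0].ci95_center
        assert hi - lo < 1e-8

    def test_same_seed_reproducible(self):
        spec = make_spectrum([(-77.0, 20.0, 1.0)], sigma=0.02, seed=5)
        fit = fit_lorentzians(spec, 1)
        a = monte_carlo_ci(spec, fit, n_reps=60, seed=42)
        b = monte_carlo_ci(spec, fit, n_reps=60, seed=42)
        assert a.peaks[0].ci95_center == b.peaks[0].ci95_center
        assert a.peaks[0].ci95_area == b.peaks[0].ci95_area

    def test_ci_width_scales_with_noise(self):
        # halving sigma should halve the CI width (within 20%)
        widths = {}
        for sigma in (0.04, 0.02):
            spec = make_spectrum([(-77.0, 20.0, 1.0)], sigma=sigma, seed=7)
            fit = fit_lorentzians(spec, 1)
            out = monte_carlo_ci(spec, fit, n_reps=150, seed=11)
            lo, hi = out.peaks[0].ci95_center
            widths[sigma] = hi - lo
        ratio = widths[0.04] / widths[0.02]
        assert 1.6 < ratio < 2.4

    def test_too_few_reps_rejected(self):
        spec = make_spectrum([(-77.0, 20.0, 1.0)])
        fit = fit_lorentzians(spec, 1)
        with pytest.raises(ValueError):
            monte_carlo_ci(spec, fit, n_reps=10)


class TestAssignPhases:
    def _result(self, peaks):
        return DeconvolutionResult(peaks=peaks, baseline=0.0, residual_rms=0.0,
                                   converged=True)

    def test_upfield_is_lean_for_positive_theta_c(self, calibration):
        res = self._result([LorentzianPeak(-77.30, 15.0, 0.6),
                            LorentzianPeak(-77.05, 80.0, 0.4)])
        out = assign_phases(res, calibration)
        assert out.peak("lean").center == -77.30
        assert out.peak("dense").center == -77.05

    def test_coincident_centers_tie_break_by_width(self, calibration):
        res = self._result([LorentzianPeak(-77.1, 80.0, 0.4),
                            LorentzianPeak(-77.1, 15.0, 0.6)])
        out = assign_phases(res, calibration)
        assert out.peak("lean").fwhm == 15.0

    def test_component_order_invariance(self, calibration):
        a = self._result([LorentzianPeak(-77.30, 15.0, 0.6),
                          LorentzianPeak(-77.05, 80.0, 0.4)])
        b = self._result([LorentzianPeak(-77.05, 80.0, 0.4),
                          LorentzianPeak(-77.30, 15.0, 0.6)])
        out_a, out_b = assign_phases(a, calibration), assign_phases(b, calibration)
        assert out_a.peak("lean").center == out_b.peak("lean").center
        assert out_a.peak("dense").fwhm == out_b.peak("dense").fwhm

    def test_zero_theta_c_rejected(self, calibration):
        from llpsnmr.quant import CalibrationModel
        flat = CalibrationModel(delta0=-77.0, theta_C=0.0)
        res = self._result([LorentzianPeak(-77.3, 15.0, 0.6),
                            LorentzianPeak(-77.0, 80.0, 0.4)])
        with pytest.raises(ValueError, match="theta_C"):
            assign_phases(res, flat)
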