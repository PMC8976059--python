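import numpy as np
import pytest

from llpsnmr.spatial import (
    SliceProfile,
    compute_slice_geometry,
    correct_gradient_nonlinearity,
    detect_layer_onset,
    fit_settling_regimes,
    locate_boundary,
    per_slice_phase_fractions,
)
from llpsnmr.quant import predict_shift
from tests.conftest import make_spectrum


class TestSliceGeometry:
    def test_default_width_is_one_millimetre(self):
        g = compute_slice_geometry()
        assert g.slice_width_mm == pytest.approx(0.99, abs=0.01)
        assert round(g.slice_width_mm) == 1

    def test_max_offset_maps_to_5p5_mm(self):
        g = compute_slice_geometry()
        assert g.slice_centers_mm.max() == pytest.approx(5.50, abs=0.01)
        assert g.slice_centers_mm.min() == pytest.approx(-5.50, abs=0.01)

    def test_zero_offset_at_isocentre(self):
        g = compute_slice_geometry(offsets_Hz=[0.0])
        assert g.slice_centers_mm[0] == 0.0

    def test_centre_linear_in_offset(self):
        g1 = compute_slice_geometry(offsets_Hz=[10000.0])
        g3 = compute_slice_geometry(offsets_Hz=[30000.0])
        assert g3.slice_centers_mm[0] == pytest.approx(3 * g1.slice_centers_mm[0], rel=1e-12)

    def test_zero_gradient_rejected(self):
        with pytest.raises(ValueError):
            compute_slice_geometry(gradient_G_per_cm=0.0)


class TestNonlinearityCorrection:
    def _slices(self, scales):
        return [make_spectrum([(-77.0, 20.0, s)], n=512) for s in scales]

    def test_uniform_references_no_change(self):
        specs = self._slices([1.0] * 4)
        corrected, factors = correct_gradient_nonlinearity(specs, [2.0] * 4)
        np.testing.assert_allclose(factors, 1.0)
        np.testing.assert_allclose(corrected[0].intensity, specs[0].intensity)

    def test_half_reference_doubles_slice(self):
        specs = self._slices([1.0, 1.0, 1.0])
        corrected, factors = correct_gradient_nonlinearity(specs, [2.0, 1.2, 2.0])
        # mean ref of [2,1.2,2] applied: middle slice scaled by mean/1.2
        assert factors[1] == pytest.approx(np.mean([2.0, 1.2, 2.0]) / 1.2)

    def test_smooth_rolloff_recovered(self):
        # 10% sensitivity roll-off at the outer slices: probe and reference
        # scale together, so correction restores uniform probe integrals
        sens = np.array([0.90, 0.97, 1.0, 1.0, 0.97, 0.90])
        specs = self._slices(sens)
        corrected, _ = correct_gradient_nonlinearity(specs, 0.5 * sens)
        integrals = [np.trapezoid(s.intensity, s.axis_ppm) for s in corrected]
        assert np.ptp(integrals) / np.mean(integrals) < 1e-3

    def test_idempotence(self):
        sens = [0.9, 1.0, 1.1]
        specs = self._slices(sens)
        once, _ = correct_gradient_nonlinearity(specs, sens)
        refs2 = [np.trapezoid(s.intensity, s.axis_ppm) for s in once]
        twice, factors2 = correct_gradient_nonlinearity(once, refs2)
        np.testing.assert_allclose(factors2, 1.0, rtol=1e-9)

    def test_nonpositive_reference_flagged(self):
        specs = self._slices([1.0, 1.0])
        corrected, factors = correct_gradient_nonlinearity(specs, [1.0, 0.0])
        assert corrected[1] is None and np.isnan(factors[1])


class TestPerSlicePhaseFractions:
    def test_pure_lean_slice(self, calibration):
        center = predict_shift(calibration, 80.0, 15.0, 20.0)
        spec = make_spectrum([(center, 18.0, 1.0)], sigma=0.005, seed=1)
        prof = per_slice_phase_fractions([spec], calibration)
        assert prof.lean_pct[0] == 100.0 and prof.dense_pct[0] == 0.0

    def test_30_70_split_recovered(self, calibration):
        c_lean = predict_shift(calibration, 80.0, 15.0, 20.0)
        c_dense = predict_shift(calibration, 360.0, 15.0, 20.0)
        height = 2 * 0.3 / (np.pi * 18.0 / 470.0)
        spec = make_spectrum([(c_lean, 18.0, 0.3), (c_dense, 80.0, 0.7)],
                             sigma=height / 100, seed=2, n=4096)
        prof = per_slice_phase_fractions([spec], calibration)
        assert prof.lean_pct[0] == pytest.approx(30.0, abs=2.0)
        assert prof.dense_pct[0] == pytest.approx(70.0, abs=2.0)
        assert prof.lean_pct[0] + prof.dense_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_unusable_slice_propagates(self, calibration):
        prof = per_slice_phase_fractions([None], calibration)
        assert not prof.usable[0] and np.isnan(prof.lean_pct[0])


class TestLocateBoundary:
    GEOM = compute_slice_geometry()

    def _profile(self, dense_pct):
        n = len(dense_pct)
        return SliceProfile(0.0, 100 - np.asarray(dense_pct, float),
                            np.asarray(dense_pct, float), np.ones(n, bool))

    def test_symmetric_step_midpoint(self):
        geom = compute_slice_geometry(offsets_Hz=np.linspace(-93404, 93404, 12))
        # dense below -0.5mm centre (slices 0..5), lean above (6..11)
        dense = [100.0] * 6 + [0.0] * 6
        h, status = locate_boundary(self._profile(dense), geom)
        assert status == "ok"
        assert h == pytest.approx(0.0, abs=0.01)

    def test_linear_interpolation_between_slices(self):
        geom = compute_slice_geometry(
            offsets_Hz=[93404.0 * 4.5 / 5.5, 93404.0])  # centers +4.5, +5.5
        h, status = locate_boundary(self._profile([80.0, 20.0]), geom)
        assert h == pytest.approx(5.0, abs=0.01)

    def test_all_dense_censored_above(self):
        h, status = locate_boundary(self._profile([90.0] * 12), self.GEOM)
        assert h is None and status == "censored_above"

    def test_all_lean_censored_below(self):
        h, status = locate_boundary(self._profile([10.0] * 12), self.GEOM)
        assert h is None and status == "censored_below"

    def test_multiple_crossings_flagged_topmost(self):
        # bottom to top: a lean pocket buried in the dense layer creates
        # extra crossings below the true boundary at 0 mm
        dense = [80, 20, 80, 80, 80, 80, 20, 20, 20, 20, 20, 20]
        h, status = locate_boundary(self._profile(dense), self.GEOM)
        assert status == "multimodal"
        assert h == pytest.approx(0.0, abs=0.01)


class TestSettlingRegimes:
    def _boundary(self, times, r_fast, r_slow, bp, noise=0.0, seed=0):
        depth = np.where(times <= bp,
                         r_fast * times / 60.0,
                         r_fast * bp / 60.0 + r_slow * (times - bp) / 60.0)
        if noise:
            depth = depth + np.random.default_rng(seed).normal(0, noise, times.size)
        return depth

    def test_noiseless_exact_recovery(self):
        times = np.arange(140.0, 1900.0, 20.0)
        depth = self._boundary(times, 0.154, 0.004, 1100.0)
        fit = fit_settling_regimes(times, depth)
        assert fit.rate_fast_mm_per_hr == pytest.approx(0.154, abs=1e-10)
        assert fit.rate_slow_mm_per_hr == pytest.approx(0.004, abs=1e-10)
        assert abs(fit.breakpoint_min - 1100.0) <= 20.0  # one sample

    def test_single_slope_both_segments_agree(self):
        times = np.arange(0.0, 600.0, 30.0)
        fit = fit_settling_regimes(times, 0.1 * times / 60.0)
        assert fit.rate_fast_mm_per_hr == pytest.approx(fit.rate_slow_mm_per_hr, abs=1e-8)
        assert fit.rate_fast_mm_per_hr == pytest.approx(0.1, abs=1e-8)

    def test_noisy_recovery_within_5pct(self):
        times = np.arange(140.0, 1900.0, 20.0)
        depth = self._boundary(times, 0.154, 0.004, 1100.0, noise=0.05, seed=4)
        fit = fit_settling_regimes(times, depth)
        assert fit.rate_fast_mm_per_hr == pytest.approx(0.154, rel=0.05)

    def test_few_points_single_line_fallback(self):
        times = np.arange(0.0, 100.0, 25.0)
        fit = fit_settling_regimes(times, 0.2 * times / 60.0)
        assert fit.single_segment
        assert fit.rate_fast_mm_per_hr == pytest.approx(0.2, abs=1e-8)


class TestLayerOnset:
    def test_step_at_140_minutes(self):
        t = np.arange(0.0, 400.0, 10.0)
        w = np.where(t < 140.0, 3.0, 6.0)
        assert detect_layer_onset(t, w) == 140.0

    def test_flat_series_no_onset(self):
        t = np.arange(0.0, 400.0, 10.0)
        assert detect_layer_onset(t, np.full(t.size, 3.0)) is None

    def test_single_spike_not_onset(self):
        t = np.arange(0.0, 400.0, 10.0)
        w = np.full(t.size, 3.0)
        w[8] = 10.0  # one-point spike at t=80
        assert detect_layer_onset(t, w) is None

    def test_baseline_requires_ten_points(self):
        with pytest.raises(ValueError):
            detect_layer_onset(np.arange(5.0), np.ones(5))
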