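import numpy as np
import pytest

from llpsnmr.deconv import fit_lorentzians
from llpsnmr.quant import SYNTHETIC_CALIBRATION
from llpsnmr.simulate import (
    LLPSSimParams,
    NoiseModel,
    PRESETS,
    SettlingSimParams,
    preset,
    render_spectrum_series,
    simulate_phase_trajectory,
    simulate_slice_series,
)
from llpsnmr.spatial import compute_slice_geometry


class TestPhaseTrajectory:
    def test_mass_conservation_exact(self):
        for name in PRESETS:
            traj = simulate_phase_trajectory(preset(name))
            p = traj.attrs["params"]
            totals = traj.pivot(index="time_min", columns="phase", values="M_mg").sum(axis=1)
            np.testing.assert_allclose(totals, p.total_mass_mg, atol=1e-12 * p.total_mass_mg)

    def test_concentration_minimum_at_analytic_crossover(self):
        p = preset("45C", dt_min=0.01)
        traj = simulate_phase_trajectory(p)
        dense = traj[traj.phase == "dense"]
        t_min = dense.loc[dense.C_mgml.idxmin(), "time_min"]
        assert t_min == pytest.approx(p.analytic_crossover_min, abs=2 * p.dt_min)
        assert p.analytic_crossover_min == pytest.approx(p.crossover_min, rel=1e-12)

    def test_arrested_volume_frozen_after_maximum(self):
        traj = simulate_phase_trajectory(preset("50C-arrested"))
        p = traj.attrs["params"]
        dense = traj[traj.phase == "dense"].set_index("time_min")
        after = dense.loc[dense.index > p.crossover_min, "V_uL"]
        np.testing.assert_allclose(after, dense["V_uL"].max(), rtol=1e-12)

    def test_lag_delays_dense_growth(self):
        traj = simulate_phase_trajectory(preset("40C"))
        dense = traj[traj.phase == "dense"].set_index("time_min")
        assert (dense.loc[dense.index < 15.0, "V_uL"] == 0).all()
        assert dense.loc[20.0, "V_uL"] > 0

    def test_preset_orderings_follow_temperature(self):
        # dense end-state concentration rises, volume falls, with jump temperature
        ends = {}
        for name in ("40C", "45C", "50C-arrested"):
            traj = simulate_phase_trajectory(preset(name))
            d = traj[traj.phase == "dense"]
            ends[name] = (d.C_mgml.iloc[-1], d.V_uL.iloc[-1])
        assert ends["40C"][0] < ends["45C"][0] < ends["50C-arrested"][0]
        assert ends["40C"][1] > ends["45C"][1] > ends["50C-arrested"][1]

    def test_unphysical_parameters_rejected(self):
        with pytest.raises(ValueError):
            LLPSSimParams(C_lean_final=400.0)  # lean above dense minimum
        with pytest.raises(ValueError):
            # amplitude ratio leaves no interior concentration minimum
            LLPSSimParams(C_dense_initial=251.0, C_dense_min=250.0, C_dense_final=360.0)


class TestRenderSpectrumSeries:
    def test_area_ratio_tracks_volume_ratio(self):
        traj = simulate_phase_trajectory(preset("45C", t_max_min=60.0, dt_min=30.0))
        spectra = render_spectrum_series(traj)
        t, spec = spectra[-1]
        fit = fit_lorentzians(spec.crop(-78.5, -75.0), 2)
        wide = traj.pivot(index="time_min", columns="phase", values="V_uL")
        v_l, v_d = wide.loc[t, "lean"], wide.loc[t, "dense"]
        areas = sorted(p.area for p in fit.peaks)
        ratio_true = sorted([v_l, v_d])
        assert areas[0] / areas[1] == pytest.approx(ratio_true[0] / ratio_true[1], rel=1e-4)

    def test_centre_separation_matches_calibration(self):
        traj = simulate_phase_trajectory(preset("45C", t_max_min=60.0, dt_min=30.0))
        spectra = render_spectrum_series(traj)
        t, spec = spectra[-1]
        fit = fit_lorentzians(spec.crop(-78.5, -75.0), 2)
        wide = traj.pivot(index="time_min", columns="phase", values="C_mgml")
        dC = wide.loc[t, "dense"] - wide.loc[t, "lean"]
        centers = sorted(p.center for p in fit.peaks)
        assert centers[1] - centers[0] == pytest.approx(
            SYNTHETIC_CALIBRATION.theta_C * dC, rel=1e-4)

    def test_fixed_seed_byte_identical(self):
        traj = simulate_phase_trajectory(preset("45C", t_max_min=10.0, dt_min=5.0))
        a = render_spectrum_series(traj, noise=NoiseModel(snr=50, seed=9))
        b = render_spectrum_series(traj, noise=NoiseModel(snr=50, seed=9))
        for (_, sa), (_, sb) in zip(a, b):
            np.testing.assert_array_equal(sa.intensity, sb.intensity)

    def test_onset_broadening_applied_to_reference(self):
        traj = simulate_phase_trajectory(preset("45C", t_max_min=40.0, dt_min=20.0))
        spectra = render_spectrum_series(
            traj, noise=NoiseModel(snr=1e12, seed=0,
                                   inhomogeneity_broadening_Hz=lambda t: 5.0),
            onset_min=30.0)
        pre = fit_lorentzians(spectra[0][1].crop(-62.0, -60.0), 1)
        post = fit_lorentzians(spectra[-1][1].crop(-62.0, -60.0), 1)
        assert pre.peaks[0].fwhm == pytest.approx(3.0, abs=0.3)
        assert post.peaks[0].fwhm == pytest.approx(8.0, abs=0.3)


class TestSliceSeries:
    GEOM = compute_slice_geometry()

    def _series(self, **kw):
        traj = simulate_phase_trajectory(preset("40C", t_max_min=1900.0, dt_min=10.0))
        settling = SettlingSimParams()
        defaults = dict(noise=None, times_min=[100.0, 500.0, 1300.0], n_points=4096)
        defaults.update(kw)
        return simulate_slice_series(traj, settling, self.GEOM, **defaults), settling

    def test_pre_onset_slices_uniform(self):
        series, _ = self._series()
        t, specs, gt = series[0]
        assert t < 140.0
        assert np.ptp(gt["lean_fracs"]) == 0.0

    def test_boundary_height_follows_two_regimes(self):
        _, settling = self._series(times_min=[200.0])
        h1 = settling.boundary_height_mm(140.0)
        h2 = settling.boundary_height_mm(740.0)  # 10 hr into fast regime
        assert h1 - h2 == pytest.approx(0.154 * 10.0, rel=1e-12)
        h3 = settling.boundary_height_mm(1100.0)
        h4 = settling.boundary_height_mm(1160.0)
        assert h3 - h4 == pytest.approx(0.004 * 1.0, rel=1e-12)

    def test_topmost_slice_goes_lean_after_boundary_passes(self):
        # boundary reaches below the top slice (centre +5.5, lower edge +5.0)
        # after (6.0 - 5.0) / 0.154 hr ~ 390 min past onset
        series, _ = self._series(times_min=[600.0])
        _, specs, gt = series[0]
        assert gt["lean_fracs"][-1] >= 0.99

    def test_sensitivity_profile_scales_reference(self):
        sens = np.linspace(0.9, 1.1, 12)
        series, _ = self._series(times_min=[100.0], sensitivity=sens)
        _, specs, _ = series[0]
        refs = [np.trapezoid(s.crop(-62.0, -60.0).intensity,
                             s.crop(-62.0, -60.0).axis_ppm) for s in specs]
        np.testing.assert_allclose(np.array(refs) / refs[0], sens / sens[0], rtol=1e-3)

    def test_times_outside_trajectory_rejected(self):
        with pytest.raises(ValueError, match="span"):
            self._series(times_min=[5000.0])
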