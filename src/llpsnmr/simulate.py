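"""Synthetic ground-truth trajectories, spectra and decay series.

No instrument data ships with the package, so every pipeline stage is
exercised against a simulator that emulates the staged phenomenology of a
temperature-triggered protein LLPS experiment followed by a fluorinated
probe:

* a dense phase nucleates at high concentration after an optional lag,
  dilutes while its volume grows, passes through a crossover (minimum
  concentration, maximum volume), then compacts — with the lean phase
  concentration derived from exact mass conservation at every step;
* spectra carry a probe resonance near -77 ppm whose position is linear in
  local protein concentration (one narrow lean line upfield of a broad
  dense line), plus a concentration-insensitive reference near -61 ppm
  that broadens only when macroscopic layering degrades field homogeneity;
* after layer-separation onset the dense layer's upper boundary sinks
  through the slice stack at a fast and then a slow constant rate, with a
  trapped lean remnant bleeding out of the dense layer;
* relaxation/diffusion decay series follow the standard inversion-recovery,
  CPMG and Stejskal-Tanner forms.

The dense-concentration trajectory is the two-exponential form

    C_d(t) = C_min + (C_init - C_min) e^{-s/tau1} + (C_final - C_min)(1 - e^{-s/tau2})

with s = (t - lag)_+ and tau2 = 5 tau1, for which the time of the minimum
has the closed form s* = 1.25 tau1 ln(5 (C_init - C_min)/(C_final - C_min));
tau1 is chosen so s* lands on the requested crossover time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum1D, AcquisitionMeta, DecaySeries, DEFAULT_FREQ_19F_MHZ
from .deconv import lorentzian_profile
from .quant import CalibrationModel, SYNTHETIC_CALIBRATION, predict_shift
from .biophys import GAMMA_19F_HZ_PER_T
from .spatial import SliceGeometry

__all__ = [
    "LLPSSimParams",
    "SettlingSimParams",
    "NoiseModel",
    "WidthModel",
    "PRESETS",
    "preset",
    "simulate_phase_trajectory",
    "render_spectrum_series",
    "simulate_slice_series",
    "simulate_decay_series",
]

TAU2_OVER_TAU1 = 5.0
TFT_CENTER_PPM = -61.0
TFT_FWHM_HZ = 3.0


@dataclass
class LLPSSimParams:
    """Ground-truth trajectory parameters for one temperature-jump run."""

    total_concentration: float = 200.0  # mg/mL loaded protein
    V_O: float = 236.8  # uL, NMR-observed volume (bulk detection)
    temperature_C: float = 45.0
    lag_min: float = 0.0
    crossover_min: float = 40.0
    C_dense_initial: float = 340.0
    C_dense_min: float = 250.0
    C_dense_final: float = 360.0
    C_lean_final: float = 80.0
    arrested: bool = False
    dt_min: float = 0.5
    t_max_min: float = 120.0
    Y_mM: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("total_concentration", "C_dense_initial", "C_dense_min",
                     "C_dense_final", "C_lean_final"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.C_dense_min <= min(self.C_dense_initial, self.C_dense_final)):
            raise ValueError("C_dense_min must not exceed the initial/final dense concentrations")
        if self.C_lean_final >= self.C_dense_min:
            raise ValueError("C_lean_final must lie below C_dense_min")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")
        if self.crossover_min <= self.lag_min:
            raise ValueError("crossover must come after the lag")
        A = self.C_dense_initial - self.C_dense_min
        B = self.C_dense_final - self.C_dense_min
        if TAU2_OVER_TAU1 * A <= B:
            raise ValueError("no interior concentration minimum for these amplitudes")

    @property
    def tau1_min(self) -> float:
        A = self.C_dense_initial - self.C_dense_min
        B = self.C_dense_final - self.C_dense_min
        s_star = self.crossover_min - self.lag_min
        r = TAU2_OVER_TAU1
        return s_star * (1 - 1 / r) / np.log(r * A / B)

    @property
    def tau2_min(self) -> float:
        return TAU2_OVER_TAU1 * self.tau1_min

    @property
    def analytic_crossover_min(self) -> float:
        """Time of the dense-concentration minimum (equals crossover_min by construction)."""
        A = self.C_dense_initial - self.C_dense_min
        B = self.C_dense_final - self.C_dense_min
        r = self.tau2_min / self.tau1_min
        s = np.log(r * A / B) / (1 / self.tau1_min - 1 / self.tau2_min)
        return self.lag_min + s

    @property
    def total_mass_mg(self) -> float:
        return self.total_concentration * self.V_O / 1000.0

    @property
    def C_dense_at_crossover(self) -> float:
        """Achieved dense-concentration minimum (above the C_dense_min asymptote)."""
        s = self.crossover_min - self.lag_min
        A = self.C_dense_initial - self.C_dense_min
        B = self.C_dense_final - self.C_dense_min
        return self.C_dense_min + A * np.exp(-s / self.tau1_min) + B * (
            1 - np.exp(-s / self.tau2_min))

    def lever_volume_uL(self, C_dense: float) -> float:
        """Tie-line dense volume at dense concentration C_dense with the lean
        phase at its equilibrium concentration C_lean_final."""
        return (self.total_concentration - self.C_lean_final) / (
            C_dense - self.C_lean_final) * self.V_O

    @property
    def V_dense_max_uL(self) -> float:
        """Dense volume at the crossover (tie-line at the concentration minimum)."""
        return self.lever_volume_uL(self.C_dense_at_crossover)


@dataclass
class SettlingSimParams:
    """Boundary settling after layer-separation onset."""

    onset_min: float = 140.0
    rate_fast_mm_per_hr: float = 0.154
    rate_slow_mm_per_hr: float = 0.004
    breakpoint_min: float = 1100.0
    start_height_mm: float = 6.0  # boundary enters at the top of the slice window
    trapped_lean_frac_initial: float = 0.20
    trapped_decay_tau_min: float = 400.0

    def __post_init__(self) -> None:
        if self.rate_fast_mm_per_hr < 0 or self.rate_slow_mm_per_hr < 0:
            raise ValueError("settling rates must be non-negative")
        if self.breakpoint_min <= self.onset_min:
            raise ValueError("breakpoint must come after onset")

    def boundary_height_mm(self, t_min) -> np.ndarray:
        """Boundary height (mm above isocentre, positive up) vs time."""
        t = np.asarray(t_min, dtype=float)
        dt_fast = np.clip(t - self.onset_min, 0.0, self.breakpoint_min - self.onset_min)
        dt_slow = np.clip(t - self.breakpoint_min, 0.0, None)
        drop = self.rate_fast_mm_per_hr * dt_fast / 60.0 + self.rate_slow_mm_per_hr * dt_slow / 60.0
        return self.start_height_mm - drop


@dataclass
class NoiseModel:
    """Frequency-domain noise and post-onset inhomogeneity broadening."""

    snr: float = 100.0  # tallest-peak amplitude / noise sigma
    seed: int = 0
    inhomogeneity_broadening_Hz: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    def extra_width(self, t_min: float) -> float:
        if self.inhomogeneity_broadening_Hz is None:
            return 0.0
        return float(self.inhomogeneity_broadening_Hz(t_min))


@dataclass
class WidthModel:
    """Probe linewidth as a linear function of local protein concentration."""

    intercept_Hz: float = 5.0
    slope_Hz_per_mgml: float = 0.2

    def fwhm(self, C_mgml: float) -> float:
        return self.intercept_Hz + self.slope_Hz_per_mgml * C_mgml


PRESETS = {
    # lag/crossover/concentration anchors chosen so dense final concentration
    # rises, and dense final volume falls, with jump temperature; the 40C run
    # carries the 15 min volume lag and a late crossover.
    "40C": LLPSSimParams(temperature_C=40.0, lag_min=15.0, crossover_min=100.0,
                         C_dense_initial=320.0, C_dense_min=240.0, C_dense_final=340.0),
    "45C": LLPSSimParams(temperature_C=45.0, lag_min=0.0, crossover_min=40.0,
                         C_dense_initial=340.0, C_dense_min=250.0, C_dense_final=360.0),
    "50C-arrested": LLPSSimParams(temperature_C=50.0, lag_min=0.0, crossover_min=25.0,
                                  C_dense_initial=330.0, C_dense_min=300.0,
                                  C_dense_final=380.0, arrested=True),
}


def preset(name: str, **overrides) -> LLPSSimParams:
    """A named preset, optionally with field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def _dense_concentration(p: LLPSSimParams, t: np.ndarray) -> np.ndarray:
    s = np.clip(t - p.lag_min, 0.0, None)
    A = p.C_dense_initial - p.C_dense_min
    B = p.C_dense_final - p.C_dense_min
    return p.C_dense_min + A * np.exp(-s / p.tau1_min) + B * (1 - np.exp(-s / p.tau2_min))


def _dense_volume(p: LLPSSimParams, t: np.ndarray) -> np.ndarray:
    """Sigmoidal growth to the crossover maximum, then tie-line compaction.

    After the crossover the dense volume follows the lever rule at the
    current dense concentration (lean phase pinned at its equilibrium
    concentration), so compaction shrinks the volume exactly as the dense
    phase densifies; in arrested mode the volume freezes at its maximum.
    """
    s_star = p.crossover_min - p.lag_min
    v = np.zeros_like(t, dtype=float)
    rising = (t >= p.lag_min) & (t <= p.crossover_min)
    s = t[rising] - p.lag_min
    v[rising] = p.V_dense_max_uL * np.sin(0.5 * np.pi * s / s_star) ** 2
    after = t > p.crossover_min
    if p.arrested:
        v[after] = p.V_dense_max_uL
    else:
        v[after] = p.lever_volume_uL(_dense_concentration(p, t[after]))
    return v


def simulate_phase_trajectory(params: LLPSSimParams) -> pd.DataFrame:
    """Ground-truth phase trajectory with exact mass conservation.

    Returns a long-format table (time_min, phase, C_mgml, V_uL, M_mg); the
    lean concentration is derived from conservation,
    C_l = (M_total - C_d V_d) / (V_O - V_d), so lean + dense mass equals
    the loaded mass at every time by construction.  Parameter combinations
    that would drive the lean concentration negative anywhere on the time
    grid are rejected before any data is returned.
    """
    p = params
    t = np.arange(0.0, p.t_max_min + 0.5 * p.dt_min, p.dt_min)
    C_d = _dense_concentration(p, t)
    V_d = _dense_volume(p, t)
    pre = t < p.lag_min
    C_d = np.where(pre, p.C_dense_initial, C_d)
    if np.any(V_d >= p.V_O):
        raise ValueError("dense volume reaches the observed volume; reduce C amplitudes")
    M_tot = p.total_mass_mg
    M_d = C_d * V_d / 1000.0
    V_l = p.V_O - V_d
    C_l = (M_tot - M_d) * 1000.0 / V_l
    if np.any(C_l < 0):
        raise ValueError("parameters drive the lean concentration negative")
    M_l = C_l * V_l / 1000.0
    frames = []
    for phase, C, V, M in (("lean", C_l, V_l, M_l), ("dense", C_d, V_d, M_d)):
        frames.append(pd.DataFrame({
            "time_min": t, "phase": phase, "C_mgml": C, "V_uL": V, "M_mg": M,
        }))
    out = pd.concat(frames, ignore_index=True).sort_values(
        ["time_min", "phase"], ignore_index=True)
    out.attrs["params"] = p
    return out


def _pivot(trajectory: pd.DataFrame) -> pd.DataFrame:
    return trajectory.pivot(index="time_min", columns="phase",
                            values=["C_mgml", "V_uL", "M_mg"])


def _render_one(
    axis: np.ndarray,
    components: Sequence,  # (center_ppm, fwhm_Hz, area)
    sigma: float,
    rng: np.random.Generator,
    meta: AcquisitionMeta,
) -> Spectrum1D:
    y = np.zeros_like(axis)
    for c, w, a in components:
        if a > 0:
            y = y + lorentzian_profile(axis, c, w, a, meta.spectrometer_freq_19F)
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, axis.size)
    return Spectrum1D(axis, y, meta)


def render_spectrum_series(
    trajectory: pd.DataFrame,
    calibration: CalibrationModel = SYNTHETIC_CALIBRATION,
    noise: NoiseModel = None,
    widths: WidthModel = None,
    temperature_C: Optional[float] = None,
    Y_mM: float = 20.0,
    axis_ppm: tuple = (-88.0, -58.0),
    n_points: int = 32768,
    total_probe_area: float = 1.0,
    tft_area: float = 0.5,
    onset_min: Optional[float] = None,
    freq_MHz: float = DEFAULT_FREQ_19F_MHZ,
) -> list:
    """Render the trajectory as a list of (time_min, Spectrum1D).

    Each spectrum carries the probe resonances of both phases (centre from
    the calibration at each phase's concentration, area proportional to its
    volume, width from the concentration-dependent width model) plus the
    concentration-insensitive reference line.  After ``onset_min`` the
    reference and probe widths gain the noise model's inhomogeneity
    broadening.  Noise is i.i.d. Gaussian at the stated SNR (tallest peak /
    sigma), seeded.
    """
    noise = noise or NoiseModel(snr=1e12)  # effectively noiseless default
    widths = widths or WidthModel()
    p = trajectory.attrs.get("params")
    if temperature_C is None:
        temperature_C = p.temperature_C if p is not None else 25.0
    V_O = p.V_O if p is not None else float(trajectory.groupby("time_min")["V_uL"].sum().iloc[0])
    dT = temperature_C - calibration.ref_temperature_C
    axis = np.linspace(axis_ppm[0], axis_ppm[1], n_points)
    rng = np.random.default_rng(noise.seed)
    wide = _pivot(trajectory)
    out = []
    for t_min, row in wide.iterrows():
        extra = noise.extra_width(t_min) if (onset_min is not None and t_min >= onset_min) else 0.0
        comps = [(TFT_CENTER_PPM, TFT_FWHM_HZ + extra, tft_area)]
        probe_heights = []
        for phase in ("lean", "dense"):
            C = row[("C_mgml", phase)]
            V = row[("V_uL", phase)]
            if V <= 0:
                continue
            center = predict_shift(calibration, C, dT, Y_mM)
            fw = widths.fwhm(C) + extra
            area = total_probe_area * V / V_O
            comps.append((center, fw, area))
            probe_heights.append(2 * area / (np.pi * fw / freq_MHz))
        # SNR is referenced to the tallest *probe* resonance; the reference
        # compound sits in a separate insert and is typically far stronger
        sigma = max(probe_heights) / noise.snr
        meta = AcquisitionMeta(spectrometer_freq_19F=freq_MHz, time_min=float(t_min),
                               temperature_C=temperature_C)
        out.append((float(t_min), _render_one(axis, comps, sigma, rng, meta)))
    return out


def simulate_slice_series(
    trajectory: pd.DataFrame,
    settling: SettlingSimParams,
    geometry: SliceGeometry,
    noise: NoiseModel = None,
    calibration: CalibrationModel = SYNTHETIC_CALIBRATION,
    widths: WidthModel = None,
    times_min: Optional[Sequence] = None,
    sensitivity: Optional[Sequence] = None,
    Y_mM: float = 20.0,
    axis_ppm: tuple = (-80.0, -58.0),
    n_points: int = 8192,
    tft_area_per_slice: float = 0.5,
    freq_MHz: float = DEFAULT_FREQ_19F_MHZ,
) -> list:
    """Render spatially-selective slice spectra over time.

    Before the settling onset every slice carries the bulk lean/dense
    mixture; afterwards the dense layer's upper boundary sinks at the fast
    and then the slow rate, slices above the boundary are pure lean, and
    slices below are dense with a trapped lean remnant decaying
    exponentially.  An optional per-slice ``sensitivity`` profile scales
    both probe and reference signals, emulating gradient nonlinearity (the
    reference integrals then allow its correction).

    Returns a list of (time_min, [Spectrum1D per slice], ground_truth dict)
    where ground_truth holds the boundary height and per-slice fractions.
    """
    noise = noise or NoiseModel(snr=1e12)
    widths = widths or WidthModel()
    p = trajectory.attrs.get("params")
    if p is None:
        raise ValueError("trajectory must come from simulate_phase_trajectory")
    wide = _pivot(trajectory)
    t_traj = wide.index.to_numpy(float)
    if times_min is None:
        times_min = np.arange(settling.onset_min - 60.0, min(t_traj[-1], settling.breakpoint_min + 600.0) + 1, 30.0)
    times_min = np.asarray(times_min, dtype=float)
    if times_min.min() < t_traj[0] or times_min.max() > t_traj[-1]:
        raise ValueError("requested slice times fall outside the trajectory span")
    if sensitivity is None:
        sensitivity = np.ones(geometry.n_slices)
    sensitivity = np.asarray(sensitivity, dtype=float)
    if sensitivity.size != geometry.n_slices:
        raise ValueError("sensitivity profile length must match the slice count")
    dT = p.temperature_C - calibration.ref_temperature_C
    axis = np.linspace(axis_ppm[0], axis_ppm[1], n_points)
    rng = np.random.default_rng(noise.seed)
    half_w = geometry.slice_width_mm / 2.0
    out = []
    for t in times_min:
        C_l = float(np.interp(t, t_traj, wide[("C_mgml", "lean")].to_numpy(float)))
        C_d = float(np.interp(t, t_traj, wide[("C_mgml", "dense")].to_numpy(float)))
        V_l = float(np.interp(t, t_traj, wide[("V_uL", "lean")].to_numpy(float)))
        V_d = float(np.interp(t, t_traj, wide[("V_uL", "dense")].to_numpy(float)))
        bulk_lean = V_l / p.V_O
        extra = noise.extra_width(t) if t >= settling.onset_min else 0.0
        if t < settling.onset_min:
            lean_fracs = np.full(geometry.n_slices, bulk_lean)
            h_b = None
        else:
            h_b = float(settling.boundary_height_mm(t))
            tl = settling.trapped_lean_frac_initial * np.exp(
                -(t - settling.onset_min) / settling.trapped_decay_tau_min)
            frac_below = np.clip((h_b - (geometry.slice_centers_mm - half_w)) /
                                 geometry.slice_width_mm, 0.0, 1.0)
            # below the boundary: dense layer with trapped lean; above: pure lean
            lean_fracs = (1.0 - frac_below) + frac_below * tl
        dense_fracs = 1.0 - lean_fracs
        specs = []
        for k in range(geometry.n_slices):
            sens = sensitivity[k]
            comps = [(TFT_CENTER_PPM, TFT_FWHM_HZ + extra, tft_area_per_slice * sens)]
            area_slice = 1.0  # probe area per fully-excited slice, a.u.
            if lean_fracs[k] > 0:
                comps.append((predict_shift(calibration, C_l, dT, Y_mM),
                              widths.fwhm(C_l) + extra, area_slice * lean_fracs[k] * sens))
            if dense_fracs[k] > 0:
                comps.append((predict_shift(calibration, C_d, dT, Y_mM),
                              widths.fwhm(C_d) + extra, area_slice * dense_fracs[k] * sens))
            probe_heights = [2 * a / (np.pi * w / freq_MHz) for _, w, a in comps[1:]]
            if not probe_heights:
                probe_heights = [2 * comps[0][2] / (np.pi * comps[0][1] / freq_MHz)]
            sigma = max(probe_heights) / noise.snr
            meta = AcquisitionMeta(spectrometer_freq_19F=freq_MHz, time_min=float(t),
                                   temperature_C=p.temperature_C, slice_index=k)
            specs.append(_render_one(axis, comps, sigma, rng, meta))
        out.append((float(t), specs, {
            "boundary_height_mm": h_b,
            "lean_fracs": lean_fracs.copy(),
            "dense_fracs": dense_fracs.copy(),
        }))
    return out


def simulate_decay_series(
    kind: str,
    true_parameter: float,
    n_points: Optional[int] = None,
    noise_frac: float = 0.0,
    seed: int = 0,
    amplitude: float = 1.0,
    big_delta_s: float = 0.150,
    little_delta_s: float = 1.5e-3,
) -> DecaySeries:
    """Generate an inversion-recovery, CPMG or PFG decay series.

    Default point counts follow standard practice for these experiments:
    8 (inversion recovery), 16 (CPMG), 16 gradient increments (PFG).
    ``true_parameter`` is R1 or R2 in 1/s, or D in m^2/s for pfg.  Noise is
    Gaussian with sigma = noise_frac * amplitude, seeded.
    """
    if true_parameter <= 0:
        raise ValueError("true_parameter must be positive")
    rng = np.random.default_rng(seed)
    if kind == "inversion_recovery":
        n = n_points or 8
        # log-spaced delays to ~5*T1, the standard recovery-curve design
        t = np.geomspace(0.02, 5.0, n) / true_parameter
        y = amplitude * (1 - 2 * np.exp(-t * true_parameter))
        series = DecaySeries(t, y + rng.normal(0, noise_frac * amplitude, n), kind)
    elif kind == "cpmg":
        n = n_points or 16
        t = np.linspace(0.05, 3.0, n) / true_parameter
        y = amplitude * np.exp(-t * true_parameter)
        series = DecaySeries(t, y + rng.normal(0, noise_frac * amplitude, n), kind)
    elif kind == "pfg":
        n = n_points or 16
        gamma = 2 * np.pi * GAMMA_19F_HZ_PER_T
        b_per_D = (gamma * little_delta_s) ** 2 * (big_delta_s - little_delta_s / 3.0)
        g_max = np.sqrt(3.0 / (b_per_D * true_parameter))  # ~95% attenuation
        g = np.linspace(0.02, 1.0, n) * g_max
        y = amplitude * np.exp(-true_parameter * b_per_D * g ** 2)
        series = DecaySeries(g, y + rng.normal(0, noise_frac * amplitude, n), kind,
                             big_delta_s=big_delta_s, little_delta_s=little_delta_s)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return series
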