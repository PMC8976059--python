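"""Assembly of phase trajectories and extraction of kinetic features.

Per-time deconvolution results are converted into phase states
(concentration via the shift calibration, volume via the integral ratio,
mass as their product), and three kinetic features are extracted:

* the crossover point, where the dense phase passes through its minimum
  concentration and maximum volume before compacting;
* the lag time before the dense-phase volume starts growing;
* the growth exponent of the dense-phase volume (log-log slope), which is
  near 1/3 for coalescence-limited coarsening and decreases when growth is
  arrested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import (
    CalibrationModel,
    ValueCI,
    phase_mass,
    phase_volume,
    shift_to_concentration,
)

__all__ = [
    "KineticsSummary",
    "build_phase_trajectories",
    "find_crossover",
    "estimate_lag",
    "fit_growth_exponent",
]


@dataclass
class KineticsSummary:
    """Extracted kinetic features of one run."""

    crossover_min: Optional[float] = None
    crossover_discordant: bool = False
    crossover_volume_min: Optional[float] = None
    lag_min: Optional[float] = None
    onset_min: Optional[float] = None
    growth_exponent: Optional[float] = None
    exponent_ci95: Optional[tuple] = None

    def to_dict(self) -> dict:
        return {
            "crossover_min": self.crossover_min,
            "crossover_discordant": self.crossover_discordant,
            "crossover_volume_min": self.crossover_volume_min,
            "lag_min": self.lag_min,
            "onset_min": self.onset_min,
            "growth_exponent": self.growth_exponent,
            "exponent_ci95": list(self.exponent_ci95) if self.exponent_ci95 else None,
        }


def build_phase_trajectories(
    deconv_series: Sequence,
    calibration: CalibrationModel,
    V_O_uL: float,
    temperature_schedule=None,
    Y_mM: float = 20.0,
) -> pd.DataFrame:
    """Convert time-ordered deconvolution results into a phase trajectory table.

    ``deconv_series`` is a sequence of (time_min, DeconvolutionResult); a
    two-component result must carry lean/dense labels.  ``temperature_schedule``
    maps time to sample temperature in degC (callable or constant; default the
    calibration reference, i.e. dT = 0).  Returns a long-format DataFrame with
    columns time_min, phase, C_mgml, C_lo, C_hi, V_uL, V_lo, V_hi, M_mg,
    M_lo, M_hi.
    """
    rows = []
    for time_min, res in deconv_series:
        if temperature_schedule is None:
            dT = 0.0
        elif callable(temperature_schedule):
            dT = temperature_schedule(time_min) - calibration.ref_temperature_C
        else:
            dT = float(temperature_schedule) - calibration.ref_temperature_C
        I_T = res.total_area()
        if res.n_components == 2:
            if res.labels is None:
                raise ValueError(f"t={time_min}: two-component result lacks phase labels")
            items = [("lean", res.peak("lean")), ("dense", res.peak("dense"))]
        else:
            # pre-separation the single resonance is the homogeneous (lean-labelled) phase
            items = [("lean", res.peaks[0])]
        for phase, peak in items:
            C = shift_to_concentration(calibration, peak.center, dT, Y_mM,
                                       delta_ci=peak.ci95_center)
            I_P = ValueCI(peak.area,
                          *(peak.ci95_area if peak.ci95_area else (peak.area, peak.area)))
            V = phase_volume(I_P, I_T, V_O_uL)
            M = phase_mass(C, V)
            rows.append({
                "time_min": time_min, "phase": phase,
                "C_mgml": C.value, "C_lo": C.lo, "C_hi": C.hi,
                "V_uL": V.value, "V_lo": V.lo, "V_hi": V.hi,
                "M_mg": M.value, "M_lo": M.lo, "M_hi": M.hi,
            })
    return pd.DataFrame(rows)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge shrinkage."""
    if window <= 1:
        return y.copy()
    half = window // 2
    out = np.empty_like(y, dtype=float)
    for i in range(y.size):
        lo, hi = max(0, i - half), min(y.size, i + half + 1)
        out[i] = np.mean(y[lo:hi])
    return out


def find_crossover(
    dense: pd.DataFrame,
    smooth_window: int = 5,
    max_disagreement_samples: int = 3,
) -> KineticsSummary:
    """Locate the crossover: minimum dense concentration / maximum dense volume.

    Both series are smoothed with a centred moving average before taking
    argmin/argmax.  The concentration minimum defines the crossover; the
    volume maximum is the cross-check, and if they disagree by more than
    ``max_disagreement_samples`` samples both are reported with a
    discordance flag.  A monotone concentration series (extremum at either
    end of the window) yields no crossover — the run may still be
    pre-crossover at the end of the observation window.
    """
    d = dense.sort_values("time_min")
    t = d["time_min"].to_numpy(float)
    if t.size < 7:
        raise ValueError("need >= 7 time points")
    c = _smooth(d["C_mgml"].to_numpy(float), smooth_window)
    v = _smooth(d["V_uL"].to_numpy(float), smooth_window)
    i_c = int(np.argmin(c))
    i_v = int(np.argmax(v))
    out = KineticsSummary()
    if i_c in (0, t.size - 1):
        return out  # monotone within window: no crossover reached
    out.crossover_min = float(t[i_c])
    out.crossover_volume_min = float(t[i_v])
    out.crossover_discordant = abs(i_c - i_v) > max_disagreement_samples
    return out


def estimate_lag(dense: pd.DataFrame, threshold_frac: float = 0.05,
                 trigger_min: float = 0.0) -> Optional[float]:
    """First time the dense volume exceeds threshold_frac of its window maximum.

    Returns the lag relative to ``trigger_min``, or None if the threshold is
    never exceeded (no dense phase formed).
    """
    d = dense.sort_values("time_min")
    t = d["time_min"].to_numpy(float)
    v = d["V_uL"].to_numpy(float)
    vmax = np.nanmax(v) if v.size else 0.0
    if vmax <= 0:
        return None
    exceed = np.nonzero(v > threshold_frac * vmax)[0]
    if exceed.size == 0:
        return None
    return float(t[exceed[0]] - trigger_min)


def fit_growth_exponent(
    times_min: np.ndarray,
    values: np.ndarray,
    trigger_min: float = 0.0,
    window: Optional[tuple] = None,
) -> tuple:
    """Power-law growth exponent from an OLS fit of log(value) on log(t - trigger).

    ``window`` restricts to trigger-relative times in (lo, hi]; the default
    excludes the first 5 minutes (nucleation transient).  Non-positive
    values or times are excluded (count reported).  Returns
    (exponent, (ci_lo, ci_hi), n_excluded).
    """
    t = np.asarray(times_min, dtype=float) - trigger_min
    v = np.asarray(values, dtype=float)
    if window is None:
        window = (5.0, np.inf)
    keep = (t > 0) & (t > window[0]) & (t <= window[1]) & (v > 0) & np.isfinite(v)
    n_excluded = int((~keep).sum())
    if keep.sum() < 6:
        raise ValueError("need >= 6 positive points inside the window")
    lx, ly = np.log(t[keep]), np.log(v[keep])
    fit = stats.linregress(lx, ly)
    dof = keep.sum() - 2
    tcrit = stats.t.ppf(0.975, dof)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return float(fit.slope), (float(ci[0]), float(ci[1])), n_excluded
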