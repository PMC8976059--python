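"""Chemical-shift calibration and phase volume/concentration/mass quantification.

The probe chemical shift is linear in local protein concentration C,
temperature change dT (relative to 25 degC) and additive (YCl3)
concentration Y:

    delta = delta0 + theta_C * C + theta_T * dT + theta_Y * Y

Inverting the fitted calibration converts each deconvoluted peak position
into a phase concentration.  The deconvoluted probe integral of each phase
divided by the total probe integral gives the phase's share of the
NMR-observed volume V_O, and concentration x volume gives the apparent
protein mass per phase.  A conservation audit checks that the summed phase
masses stay at the loaded total.

Uncertainties are propagated to first order (delta method) from the peak
CIs and the calibration covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel",
    "ValueCI",
    "fit_calibration",
    "predict_shift",
    "shift_to_concentration",
    "phase_volume",
    "phase_mass",
    "check_mass_conservation",
    "SYNTHETIC_CALIBRATION",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class ValueCI(NamedTuple):
    """A scalar with a 95% confidence interval and bookkeeping flags."""

    value: float
    lo: float
    hi: float
    floored: bool = False  # value clipped at a physical bound; raw kept below
    raw: Optional[float] = None

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class CalibrationModel:
    """Linear shift calibration delta = delta0 + theta_C*C + theta_T*dT + theta_Y*Y.

    Units: delta0 ppm; theta_C ppm/(mg/mL); theta_T ppm/degC; theta_Y ppm/mM.
    ``covariance`` is the 4x4 OLS coefficient covariance in the order
    (delta0, theta_C, theta_T, theta_Y).  dT is relative to 25 degC.
    """

    delta0: float
    theta_C: float
    theta_T: float = 0.0
    theta_Y: float = 0.0
    covariance: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    ref_temperature_C: float = 25.0
    residual_std: float = 0.0

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (4, 4):
            raise ValueError("covariance must be 4x4")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eig = np.linalg.eigvalsh((self.covariance + self.covariance.T) / 2)
        if eig.min() < -1e-10 * max(1.0, eig.max()):
            raise ValueError("covariance must be positive semi-definite")

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.delta0, self.theta_C, self.theta_T, self.theta_Y])


#: Synthetic fixture coefficients (clearly not instrument-measured): chosen so
#: that the dense phase (higher C) resonates downfield of the lean phase.
SYNTHETIC_CALIBRATION = CalibrationModel(
    delta0=-77.000, theta_C=0.0025, theta_T=0.010, theta_Y=-0.005
)

_COEF_NAMES = ("delta0", "theta_C", "theta_T", "theta_Y")
_COL_FOR_COEF = {"theta_C": "C", "theta_T": "dT", "theta_Y": "Y"}


def fit_calibration(observations: pd.DataFrame) -> CalibrationModel:
    """Ordinary least squares fit of the linear shift calibration.

    ``observations`` needs columns delta (ppm), C (mg/mL), dT (degC relative
    to 25) and Y (mM).  At least 5 observations and a full-rank design are
    required; a rank-deficient design raises an error naming the coefficient
    that cannot be identified (e.g. all C equal -> theta_C).
    """
    required = {"delta", "C", "dT", "Y"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    obs = observations.dropna(subset=sorted(required))
    n = len(obs)
    if n < 5:
        raise ValueError(f"need >= 5 observations, got {n}")
    X = np.column_stack([
        np.ones(n),
        obs["C"].to_numpy(float),
        obs["dT"].to_numpy(float),
        obs["Y"].to_numpy(float),
    ])
    # name the unidentifiable coefficient before the algebra fails obscurely
    bad = [name for name in ("theta_C", "theta_T", "theta_Y")
           if np.ptp(obs[_COL_FOR_COEF[name]].to_numpy(float)) == 0]
    if bad or np.linalg.matrix_rank(X) < 4:
        which = ", ".join(bad) if bad else "intercept/collinear terms"
        raise ValueError(f"rank-deficient design: cannot identify {which}")
    y = obs["delta"].to_numpy(float)
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - 4, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return CalibrationModel(
        delta0=float(beta[0]),
        theta_C=float(beta[1]),
        theta_T=float(beta[2]),
        theta_Y=float(beta[3]),
        covariance=cov,
        residual_std=float(np.sqrt(s2)),
    )


def predict_shift(model: CalibrationModel, C: float, dT: float = 0.0, Y: float = 0.0) -> float:
    """Forward calibration: shift in ppm at concentration C, offset dT, additive Y."""
    return model.delta0 + model.theta_C * C + model.theta_T * dT + model.theta_Y * Y


def shift_to_concentration(
    model: CalibrationModel,
    delta: float,
    dT: float = 0.0,
    Y: float = 0.0,
    delta_ci: Optional[tuple] = None,
) -> ValueCI:
    """Invert the calibration: C = (delta - delta0 - theta_T*dT - theta_Y*Y)/theta_C.

    The 95% interval combines, to first order, the shift's own CI (if given)
    with the calibration coefficient covariance.  A negative concentration is
    floored at zero with the unfloored value retained in ``raw``.
    """
    if model.theta_C == 0:
        raise ZeroDivisionError(
            "theta_C = 0: the shift carries no concentration information"
        )
    num = delta - model.delta0 - model.theta_T * dT - model.theta_Y * Y
    C = num / model.theta_C
    # gradient of C wrt (delta0, theta_C, theta_T, theta_Y)
    g = np.array([
        -1.0 / model.theta_C,
        -C / model.theta_C,
        -dT / model.theta_C,
        -Y / model.theta_C,
    ])
    var = float(g @ model.covariance @ g)
    if delta_ci is not None:
        sd_delta = (delta_ci[1] - delta_ci[0]) / (2 * Z95)
        var += (sd_delta / model.theta_C) ** 2
    half = Z95 * np.sqrt(max(var, 0.0))
    floored = C < 0
    return ValueCI(
        value=0.0 if floored else C,
        lo=C - half,
        hi=C + half,
        floored=floored,
        raw=C,
    )


def phase_volume(I_P, I_T, V_O: float) -> ValueCI:
    """Phase volume V_P = (I_P / I_T) * V_O in uL.

    ``I_P`` and ``I_T`` may be plain floats or ValueCI; integral CIs are
    propagated by the first-order ratio formula.  I_P > I_T is physically
    impossible and is reported clamped with a flag (raw ratio retained).
    """
    ip, ip_sd = _value_sd(I_P)
    it, it_sd = _value_sd(I_T)
    if it <= 0:
        raise ValueError("total integral I_T must be positive")
    if ip < 0:
        raise ValueError("phase integral I_P must be non-negative")
    ratio = ip / it
    v = ratio * V_O
    rel_var = 0.0
    if ip > 0:
        rel_var = (ip_sd / ip) ** 2 + (it_sd / it) ** 2
    half = Z95 * abs(v) * np.sqrt(rel_var)
    clamped = ratio > 1.0
    return ValueCI(
        value=min(v, V_O) if clamped else v,
        lo=v - half,
        hi=v + half,
        floored=clamped,
        raw=v,
    )


def phase_mass(C_P, V_P) -> ValueCI:
    """Apparent phase mass M_P = C_P * V_P in mg (C in mg/mL, V in uL)."""
    c, c_sd = _value_sd(C_P)
    v, v_sd = _value_sd(V_P)
    m = c * v / 1000.0
    rel_var = 0.0
    if c != 0 and v != 0:
        rel_var = (c_sd / c) ** 2 + (v_sd / v) ** 2
    half = Z95 * abs(m) * np.sqrt(rel_var)
    return ValueCI(value=m, lo=m - half, hi=m + half)


def _value_sd(x) -> tuple:
    if isinstance(x, ValueCI):
        point = x.raw if x.raw is not None else x.value
        return float(point), (x.hi - x.lo) / (2 * Z95)
    return float(x), 0.0


def check_mass_conservation(
    trajectory: pd.DataFrame,
    expected_total_mg: float,
    tol_frac: float = 0.05,
) -> dict:
    """Audit total (lean + dense) mass against the loaded protein mass.

    ``trajectory`` is the long-format table produced by the kinetics module
    (columns time_min, phase, M_mg).  Times missing either phase are
    excluded and listed.  Returns flagged times, the maximum fractional
    deviation, and the per-time totals.
    """
    if expected_total_mg <= 0:
        raise ValueError("expected_total_mg must be positive")
    piv = trajectory.pivot_table(index="time_min", columns="phase", values="M_mg", aggfunc="sum")
    have_both = piv.notna().all(axis=1) if set(piv.columns) >= {"lean", "dense"} else pd.Series(False, index=piv.index)
    excluded = piv.index[~have_both].tolist()
    totals = piv.loc[have_both].sum(axis=1)
    dev = (totals - expected_total_mg).abs() / expected_total_mg
    flagged = dev.index[dev > tol_frac].tolist()
    return {
        "expected_total_mg": expected_total_mg,
        "tol_frac": tol_frac,
        "flagged_times_min": flagged,
        "excluded_times_min": excluded,
        "max_fractional_deviation": float(dev.max()) if len(dev) else float("nan"),
        "totals": totals,
    }
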