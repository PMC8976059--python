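"""Lorentzian deconvolution of the probe region of a 1D spectrum.

During phase separation the single probe resonance splits into two
overlapping components: a narrow peak from the lean (protein-poor) phase
upfield of a broad shoulder from the dense (protein-rich) phase.  This
module fits one or two area-parameterised Lorentzians plus a constant
baseline to the probe window by bounded nonlinear least squares, selects
the number of components, estimates 95% confidence intervals by
Monte-Carlo residual resampling, and labels the components lean/dense
through the chemical-shift -> concentration calibration.

Lorentzians are parameterised by integrated area (not height) because the
area is the quantitative observable: it is proportional to the amount of
probe, and hence to the volume, of each phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .spectra import Spectrum1D, DEFAULT_FREQ_19F_MHZ

__all__ = [
    "LorentzianPeak",
    "DeconvolutionResult",
    "NoPeakError",
    "lorentzian_profile",
    "initial_guess",
    "fit_lorentzians",
    "select_n_components",
    "monte_carlo_ci",
    "assign_phases",
]

#: fit window half-width around the probe resonance, ppm
DEFAULT_PROBE_CENTER_PPM = -77.0
DEFAULT_PROBE_HALFWINDOW_PPM = 1.5

FWHM_MIN_HZ = 0.1
FWHM_MAX_HZ = 5000.0


class NoPeakError(ValueError):
    """Raised when no peak rises above the noise floor."""


@dataclass
class LorentzianPeak:
    """A fitted Lorentzian component.

    ``center`` in ppm, ``fwhm`` in Hz, ``area`` in the spectrum's intensity
    units times ppm.  CI fields are (lo, hi) 95% intervals, populated by
    :func:`monte_carlo_ci`.
    """

    center: float
    fwhm: float
    area: float
    ci95_center: Optional[tuple] = None
    ci95_fwhm: Optional[tuple] = None
    ci95_area: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.area < 0:
            raise ValueError("area must be non-negative")


@dataclass
class DeconvolutionResult:
    """Outcome of a 1- or 2-component Lorentzian fit."""

    peaks: list
    baseline: float
    residual_rms: float
    converged: bool
    freq_MHz: float = DEFAULT_FREQ_19F_MHZ
    labels: Optional[dict] = None  # {"lean": index, "dense": index}
    ci_reliable: Optional[bool] = None
    n_data: int = 0

    @property
    def n_components(self) -> int:
        return len(self.peaks)

    def peak(self, label: str) -> LorentzianPeak:
        if self.labels is None:
            raise ValueError("phases not assigned")
        return self.peaks[self.labels[label]]

    def total_area(self) -> float:
        return float(sum(p.area for p in self.peaks))

    def model(self, x: np.ndarray) -> np.ndarray:
        y = np.full_like(np.asarray(x, dtype=float), self.baseline)
        for p in self.peaks:
            y = y + lorentzian_profile(x, p.center, p.fwhm, p.area, self.freq_MHz)
        return y

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "baseline": self.baseline,
            "residual_rms": self.residual_rms,
            "converged": self.converged,
            "ci_reliable": self.ci_reliable,
            "labels": self.labels,
            "peaks": [
                {
                    "center_ppm": p.center,
                    "fwhm_Hz": p.fwhm,
                    "area": p.area,
                    "ci95_center_ppm": p.ci95_center,
                    "ci95_fwhm_Hz": p.ci95_fwhm,
                    "ci95_area": p.ci95_area,
                }
                for p in self.peaks
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def lorentzian_profile(
    x: np.ndarray,
    center: float,
    fwhm_hz: float,
    area: float,
    freq_MHz: float = DEFAULT_FREQ_19F_MHZ,
) -> np.ndarray:
    """Area-parameterised Lorentzian on a ppm axis.

    L(x) = (area/pi) * gamma / ((x - center)^2 + gamma^2) with gamma the
    half-width at half-maximum in ppm (= fwhm_hz / (2 * freq_MHz)); the
    profile integrates to ``area`` over an infinite axis.
    """
    if fwhm_hz <= 0:
        raise ValueError("fwhm must be positive")
    gamma = fwhm_hz / (2.0 * freq_MHz)
    x = np.asarray(x, dtype=float)
    return (area / np.pi) * gamma / ((x - center) ** 2 + gamma ** 2)


def _noise_mad(y: np.ndarray) -> float:
    """Robust noise sigma from the median absolute deviation of the signal-free tail."""
    med = np.median(y)
    return 1.4826 * float(np.median(np.abs(y - med)))


def _half_height_width_ppm(x: np.ndarray, y: np.ndarray, ipk: int, baseline: float) -> float:
    """Width from half-height crossings around index ipk; falls back to 4 axis steps."""
    half = baseline + 0.5 * (y[ipk] - baseline)
    left = ipk
    while left > 0 and y[left] > half:
        left -= 1
    right = ipk
    while right < y.size - 1 and y[right] > half:
        right += 1
    width = abs(x[right] - x[left])
    step = float(np.median(np.diff(x)))
    return max(width, 4 * abs(step))


def initial_guess(spectrum: Spectrum1D, n: int = 1) -> list:
    """Deterministic parameter seeds for an n-component fit.

    Returns a list of (center_ppm, fwhm_Hz, area) triples.  For n=2 the
    second seed is taken from the maximum of the smoothed residual after
    subtracting a quick single-peak fit, so a shoulder hidden under the
    main peak is still found.
    """
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    x, y = spectrum.axis_ppm, spectrum.intensity
    freq = spectrum.meta.spectrometer_freq_19F
    noise = _noise_mad(y)
    ipk = int(np.argmax(y))
    baseline = float(np.percentile(y, 10))
    if y[ipk] - baseline < 5 * max(noise, 1e-300):
        raise NoPeakError("no peak rises 5x above the noise floor")

    w_ppm = _half_height_width_ppm(x, y, ipk, baseline)
    height = y[ipk] - baseline
    # for a Lorentzian: area = height * pi * gamma
    seed1 = (float(x[ipk]), w_ppm * freq, height * np.pi * (w_ppm / 2.0))
    if n == 1:
        return [seed1]

    res = fit_lorentzians(spectrum, 1, [seed1])
    residual = y - res.model(x)
    # light smoothing so the residual maximum is not a noise spike
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(residual, kernel, mode="same")
    jpk = int(np.argmax(smooth))
    w2 = _half_height_width_ppm(x, smooth, jpk, 0.0)
    h2 = max(smooth[jpk], 0.1 * height)
    seed2 = (float(x[jpk]), w2 * freq, h2 * np.pi * (w2 / 2.0))
    return [
        (res.peaks[0].center, res.peaks[0].fwhm, res.peaks[0].area),
        seed2,
    ]


def _pack(seeds: Sequence, baseline: float) -> np.ndarray:
    theta = [baseline]
    for c, w, a in seeds:
        theta.extend([c, w, a])
    return np.array(theta, dtype=float)


def _model_from_theta(x, theta, freq):
    y = np.full(x.shape, theta[0])
    for i in range((theta.size - 1) // 3):
        c, w, a = theta[1 + 3 * i : 4 + 3 * i]
        y = y + lorentzian_profile(x, c, max(w, FWHM_MIN_HZ), a, freq)
    return y


def fit_lorentzians(
    spectrum: Spectrum1D,
    n: int,
    seeds: Optional[Sequence] = None,
    max_restarts: int = 3,
) -> DeconvolutionResult:
    """Bounded least-squares fit of n Lorentzians plus a constant baseline.

    Bounds: centers inside the axis range, FWHM in [0.1, 5000] Hz, areas
    non-negative.  On non-convergence the fit is restarted from perturbed
    seeds a bounded number of times; a still-unconverged result is returned
    flagged, never silently.
    """
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    x, y = spectrum.axis_ppm, spectrum.intensity
    freq = spectrum.meta.spectrometer_freq_19F
    if seeds is None:
        seeds = initial_guess(spectrum, n)
    if len(seeds) != n:
        raise ValueError(f"expected {n} seeds, got {len(seeds)}")
    for c, _, _ in seeds:
        if not (x[0] <= c <= x[-1]):
            raise ValueError(f"seed center {c} outside axis range [{x[0]}, {x[-1]}]")

    lo = [-np.inf] + [x[0], FWHM_MIN_HZ, 0.0] * n
    hi = [np.inf] + [x[-1], FWHM_MAX_HZ, np.inf] * n

    def resid(theta):
        return _model_from_theta(x, theta, freq) - y

    baseline0 = float(np.percentile(y, 10))
    theta0 = np.clip(_pack(seeds, baseline0), lo, hi)
    rng = np.random.default_rng(0)  # restart jitter only; fit itself deterministic
    best = None
    for attempt in range(max_restarts + 1):
        start = theta0
        if attempt > 0:
            jitter = 1.0 + 0.1 * rng.standard_normal(theta0.size)
            start = np.clip(theta0 * jitter, lo, hi)
        sol = least_squares(resid, start, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success:
            best = sol if sol.cost <= best.cost else best
            break
    theta = best.x
    peaks = [
        LorentzianPeak(center=theta[1 + 3 * i], fwhm=theta[2 + 3 * i], area=theta[3 + 3 * i])
        for i in range(n)
    ]
    rms = float(np.sqrt(np.mean(resid(theta) ** 2)))
    return DeconvolutionResult(
        peaks=peaks,
        baseline=float(theta[0]),
        residual_rms=rms,
        converged=bool(best.success),
        freq_MHz=freq,
        n_data=x.size,
    )


def _bic(n_data: int, rss: float, k: int) -> float:
    rss = max(rss, 1e-300)
    return n_data * np.log(rss / n_data) + k * np.log(n_data)


def select_n_components(spectrum: Spectrum1D, min_area_frac: float = 0.02, delta_bic: float = 10.0) -> int:
    """Choose between a 1- and 2-component model.

    Returns 2 iff the two-component fit lowers the BIC by more than
    ``delta_bic`` AND both component areas exceed ``min_area_frac`` of the
    total; this conservative rule avoids splitting a single resonance into
    two coincident components before phase separation begins.
    """
    fit1 = fit_lorentzians(spectrum, 1)
    try:
        fit2 = fit_lorentzians(spectrum, 2)
    except (NoPeakError, ValueError):
        fit2 = None
    if not fit1.converged and (fit2 is None or not fit2.converged):
        raise RuntimeError("neither the 1- nor the 2-component model converged")
    if fit2 is None or not fit2.converged:
        return 1
    ndat = spectrum.axis_ppm.size
    bic1 = _bic(ndat, fit1.residual_rms ** 2 * ndat, 4)
    bic2 = _bic(ndat, fit2.residual_rms ** 2 * ndat, 7)
    total = fit2.total_area()
    if total <= 0:
        return 1
    fracs = [p.area / total for p in fit2.peaks]
    if bic1 - bic2 > delta_bic and min(fracs) > min_area_frac:
        return 2
    return 1


def monte_carlo_ci(
    spectrum: Spectrum1D,
    result: DeconvolutionResult,
    n_reps: int = 200,
    seed: int = 0,
) -> DeconvolutionResult:
    """Monte-Carlo 95% confidence intervals for the fitted parameters.

    The residual noise sigma is estimated from the fit residuals; ``n_reps``
    synthetic datasets (model + Gaussian noise) are refit from the fitted
    parameters and the 2.5/97.5 percentiles of each parameter form the CI.
    If more than 20% of replicates fail to converge the intervals are
    flagged unreliable.  Reproducible under a fixed seed.
    """
    if not result.converged:
        raise ValueError("cannot bootstrap an unconverged fit")
    if n_reps < 50:
        raise ValueError("n_reps must be >= 50")
    x, y = spectrum.axis_ppm, spectrum.intensity
    model = result.model(x)
    sigma = float(np.std(y - model))
    rng = np.random.default_rng(seed)
    seeds = [(p.center, p.fwhm, p.area) for p in result.peaks]
    n = result.n_components
    samples = []
    n_fail = 0
    for _ in range(n_reps):
        fake = Spectrum1D(x, model + rng.normal(0.0, sigma, x.size) if sigma > 0 else model.copy(),
                          spectrum.meta)
        rep = fit_lorentzians(fake, n, seeds, max_restarts=0)
        if not rep.converged:
            n_fail += 1
            continue
        # keep replicate components aligned with the point-estimate components
        order = _match_components(result.peaks, rep.peaks)
        samples.append([
            (rep.peaks[j].center, rep.peaks[j].fwhm, rep.peaks[j].area) for j in order
        ])
    if not samples:
        raise RuntimeError("all Monte-Carlo replicates failed to converge")
    arr = np.array(samples)  # (reps, n, 3)
    peaks = []
    for i, p in enumerate(result.peaks):
        los = np.percentile(arr[:, i, :], 2.5, axis=0)
        his = np.percentile(arr[:, i, :], 97.5, axis=0)
        peaks.append(
            LorentzianPeak(
                center=p.center,
                fwhm=p.fwhm,
                area=p.area,
                ci95_center=(min(los[0], p.center), max(his[0], p.center)),
                ci95_fwhm=(min(los[1], p.fwhm), max(his[1], p.fwhm)),
                ci95_area=(min(los[2], p.area), max(his[2], p.area)),
            )
        )
    out = DeconvolutionResult(
        peaks=peaks,
        baseline=result.baseline,
        residual_rms=result.residual_rms,
        converged=result.converged,
        freq_MHz=result.freq_MHz,
        labels=result.labels,
        ci_reliable=(n_fail / n_reps) <= 0.20,
        n_data=result.n_data,
    )
    return out


def _match_components(ref_peaks, rep_peaks) -> list:
    """Greedy nearest-center matching of replicate components to the reference."""
    n = len(ref_peaks)
    if n == 1:
        return [0]
    d = np.array([[abs(r.center - p.center) for r in rep_peaks] for p in ref_peaks])
    if d[0, 0] + d[1, 1] <= d[0, 1] + d[1, 0]:
        return [0, 1]
    return [1, 0]


def assign_phases(result: DeconvolutionResult, calibration) -> DeconvolutionResult:
    """Label the two components lean/dense by calibrated concentration.

    Each center is converted to a local protein concentration through the
    shift calibration; the lower-concentration component is the lean phase.
    When the calibrated concentrations are indistinguishable (centers closer
    than the overlap of their fit CIs, or coincident), the narrower
    component is labelled lean, matching the phenomenology that the lean
    phase gives the narrow resonance.
    """
    if result.n_components != 2:
        raise ValueError("phase labels require a two-component result")
    if calibration.theta_C == 0:
        raise ValueError("calibration has theta_C = 0; concentrations are unidentifiable")
    concs = []
    for p in result.peaks:
        c = (p.center - calibration.delta0) / calibration.theta_C  # dT=Y=0 offsets cancel in ordering
        concs.append(c)
    tie = _centers_tied(result)
    if tie:
        order = np.argsort([p.fwhm for p in result.peaks])
    else:
        order = np.argsort(concs)
    labels = {"lean": int(order[0]), "dense": int(order[1])}
    return DeconvolutionResult(
        peaks=result.peaks,
        baseline=result.baseline,
        residual_rms=result.residual_rms,
        converged=result.converged,
        freq_MHz=result.freq_MHz,
        labels=labels,
        ci_reliable=result.ci_reliable,
        n_data=result.n_data,
    )


def _centers_tied(result: DeconvolutionResult) -> bool:
    p0, p1 = result.peaks
    dc = abs(p0.center - p1.center)
    if dc == 0:
        return True
    if p0.ci95_center and p1.ci95_center:
        half0 = (p0.ci95_center[1] - p0.ci95_center[0]) / 2.0
        half1 = (p1.ci95_center[1] - p1.ci95_center[0]) / 2.0
        return dc < (half0 + half1)
    return False
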