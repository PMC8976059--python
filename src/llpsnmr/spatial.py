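"""Spatially-selective slice analysis of macroscopic layer separation.

A selective pulse of bandwidth B applied during a z-gradient G excites a
horizontal slice of width B / (gamma * G); stepping the pulse offset moves
the slice along the tube.  With the instrument settings modelled here
(42.4 G/cm, 16793 Hz bandwidth, offsets up to +/-93404 Hz) this yields
twelve ~1 mm slices centred from -5.5 to +5.5 mm around the gradient
isocentre.

After the phases settle into layers, the lean/dense boundary sinks through
the stack of slices.  This module converts per-slice deconvolutions into
lean/dense volume fractions, locates the boundary as the depth where the
dense fraction crosses 50% (linear interpolation between slice centres),
fits a two-regime (fast, then slow) settling rate with an exhaustive
breakpoint search, and detects layer-separation onset from broadening of
the concentration-insensitive reference resonance, which reports on
macroscopic field inhomogeneity.

Sign convention: slice centres are heights above the gradient isocentre
(positive up, the topmost slice at +5.5 mm); boundary *depth* is the
negated height, so a sinking boundary has increasing depth and positive
settling rates in mm/hr.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum1D
from .biophys import GAMMA_19F_HZ_PER_T
from . import deconv as _dc

__all__ = [
    "SliceGeometry",
    "SliceProfile",
    "BoundaryTrajectory",
    "compute_slice_geometry",
    "correct_gradient_nonlinearity",
    "per_slice_phase_fractions",
    "locate_boundary",
    "fit_settling_regimes",
    "detect_layer_onset",
]

DEFAULT_GRADIENT_G_PER_CM = 42.4
DEFAULT_BANDWIDTH_HZ = 16793.0
DEFAULT_OFFSETS_HZ = tuple(np.linspace(-93404.0, 93404.0, 12))
DEFAULT_TOTAL_SLICE_VOLUME_UL = 130.1


@dataclass
class SliceGeometry:
    """Slice positions and widths from the gradient-excitation physics."""

    gradient_G_per_cm: float
    bandwidth_Hz: float
    offsets_Hz: np.ndarray
    slice_centers_mm: np.ndarray  # height above isocentre, positive up
    slice_width_mm: float
    slice_volume_uL: float

    @property
    def n_slices(self) -> int:
        return int(self.offsets_Hz.size)


def compute_slice_geometry(
    gradient_G_per_cm: float = DEFAULT_GRADIENT_G_PER_CM,
    bandwidth_Hz: float = DEFAULT_BANDWIDTH_HZ,
    offsets_Hz: Sequence = DEFAULT_OFFSETS_HZ,
    gamma_Hz_per_T: float = GAMMA_19F_HZ_PER_T,
    total_volume_uL: float = DEFAULT_TOTAL_SLICE_VOLUME_UL,
) -> SliceGeometry:
    """Slice width and centres from gradient strength and pulse offsets.

    width = bandwidth / (gamma * G); centre(offset) = offset / (gamma * G),
    with G converted from G/cm to T/m (42.4 G/cm = 0.424 T/m).  The observed
    volume (130.1 uL default) is distributed uniformly over the slices.
    """
    if gradient_G_per_cm <= 0:
        raise ValueError("gradient must be positive")
    offsets = np.asarray(offsets_Hz, dtype=float)
    G_T_per_m = gradient_G_per_cm * 1e-2  # 1 G/cm = 1e-2 T/m
    hz_per_m = gamma_Hz_per_T * G_T_per_m
    width_mm = bandwidth_Hz / hz_per_m * 1e3
    centers_mm = offsets / hz_per_m * 1e3
    return SliceGeometry(
        gradient_G_per_cm=gradient_G_per_cm,
        bandwidth_Hz=bandwidth_Hz,
        offsets_Hz=offsets,
        slice_centers_mm=centers_mm,
        slice_width_mm=float(width_mm),
        slice_volume_uL=total_volume_uL / offsets.size,
    )


def correct_gradient_nonlinearity(
    slice_spectra: Sequence[Spectrum1D],
    reference_integrals: Sequence[float],
) -> tuple:
    """Rescale slice spectra so the reference integral is uniform across slices.

    The reference compound fills every slice equally, so variation in its
    integral measures the per-slice excitation/detection sensitivity.  Each
    slice is scaled by mean(ref)/ref_slice; slices with non-positive
    reference integrals are flagged unusable (returned as None).
    Applying the correction twice is a no-op (recomputed factors are 1).
    """
    refs = np.asarray(reference_integrals, dtype=float)
    if refs.size != len(slice_spectra):
        raise ValueError("one reference integral per slice required")
    usable = refs > 0
    if not usable.any():
        raise ValueError("no slice has a positive reference integral")
    mean_ref = refs[usable].mean()
    corrected, factors = [], []
    for spec, ref, ok in zip(slice_spectra, refs, usable):
        if not ok:
            corrected.append(None)
            factors.append(np.nan)
            continue
        f = mean_ref / ref
        corrected.append(Spectrum1D(spec.axis_ppm.copy(), spec.intensity * f, spec.meta))
        factors.append(f)
    return corrected, np.array(factors)


@dataclass
class SliceProfile:
    """Per-slice lean/dense volume fractions (percent) at one time point."""

    time_min: float
    lean_pct: np.ndarray
    dense_pct: np.ndarray
    usable: np.ndarray

    def __post_init__(self) -> None:
        self.lean_pct = np.asarray(self.lean_pct, dtype=float)
        self.dense_pct = np.asarray(self.dense_pct, dtype=float)
        self.usable = np.asarray(self.usable, dtype=bool)


def per_slice_phase_fractions(
    corrected_spectra: Sequence,
    calibration,
    time_min: float = 0.0,
    window=None,
    Y_mM: float = 0.0,
) -> SliceProfile:
    """Deconvolve each slice and express phase integrals as percent of the slice total.

    Two-component slices split as 100*I_P/I_T.  A single-component slice is
    assigned 100% to one phase: its centre is converted to a concentration
    through the calibration and compared against the midpoint of the
    typical lean/dense fraction concentrations (nearer lean -> lean, nearer
    dense -> dense).  Unusable slices (None) propagate as missing.
    """
    lean, dense, usable = [], [], []
    for spec in corrected_spectra:
        if spec is None:
            lean.append(np.nan)
            dense.append(np.nan)
            usable.append(False)
            continue
        work = spec if window is None else spec.crop(*window)
        try:
            n = _dc.select_n_components(work)
            fit = _dc.fit_lorentzians(work, n)
        except (_dc.NoPeakError, RuntimeError):
            lean.append(np.nan)
            dense.append(np.nan)
            usable.append(False)
            continue
        if n == 2:
            fit = _dc.assign_phases(fit, calibration)
            total = fit.total_area()
            lean.append(100.0 * fit.peak("lean").area / total)
            dense.append(100.0 * fit.peak("dense").area / total)
        else:
            p = fit.peaks[0]
            dT = spec.meta.temperature_C - calibration.ref_temperature_C
            conc = (p.center - calibration.delta0 - calibration.theta_T * dT
                    - calibration.theta_Y * Y_mM) / calibration.theta_C
            # single component: all volume in the phase its concentration indicates
            midpoint = _single_component_midpoint(calibration)
            if conc >= midpoint:
                lean.append(0.0)
                dense.append(100.0)
            else:
                lean.append(100.0)
                dense.append(0.0)
        usable.append(True)
    return SliceProfile(time_min=time_min, lean_pct=np.array(lean),
                        dense_pct=np.array(dense), usable=np.array(usable))


def _single_component_midpoint(calibration, lean_C: float = 80.0, dense_C: float = 360.0) -> float:
    # midpoint of typical lean/dense fraction concentrations; config via partial
    return 0.5 * (lean_C + dense_C)


@dataclass
class BoundaryTrajectory:
    """Boundary depth vs time with fitted settling regimes."""

    times_min: np.ndarray
    depth_mm: np.ndarray  # positive down
    censored: np.ndarray  # +1 above window, -1 below, 0 observed
    rate_fast_mm_per_hr: Optional[float] = None
    rate_slow_mm_per_hr: Optional[float] = None
    breakpoint_min: Optional[float] = None
    single_segment: bool = False


def locate_boundary(profile: SliceProfile, geometry: SliceGeometry):
    """Height (mm, positive up) where the dense fraction crosses 50%.

    Linear interpolation between adjacent slice centres, scanning from the
    top of the stack; if every usable slice is >= 50% dense the boundary is
    above the observed window ('censored above'), if all are < 50% it is
    below.  Multiple crossings return the topmost with a multimodality flag.

    Returns (height_mm_or_None, status) with status in
    {'ok', 'multimodal', 'censored_above', 'censored_below'}.
    """
    ok = profile.usable & np.isfinite(profile.dense_pct)
    if ok.sum() < 2:
        raise ValueError("need at least 2 usable slices")
    centers = geometry.slice_centers_mm[ok]
    dense = profile.dense_pct[ok]
    order = np.argsort(centers)[::-1]  # top first
    centers, dense = centers[order], dense[order]
    above = dense >= 50.0
    if above.all():
        return None, "censored_above"
    if not above.any():
        return None, "censored_below"
    crossings = []
    for i in range(len(dense) - 1):
        d0, d1 = dense[i], dense[i + 1]
        if (d0 - 50.0) * (d1 - 50.0) < 0 or d0 == 50.0:
            if d0 == 50.0:
                crossings.append(centers[i])
            else:
                frac = (50.0 - d0) / (d1 - d0)
                crossings.append(centers[i] + frac * (centers[i + 1] - centers[i]))
    if not crossings:  # exact 50 at the last slice
        crossings.append(centers[-1])
    status = "ok" if len(crossings) == 1 else "multimodal"
    return float(crossings[0]), status


def fit_settling_regimes(times_min: np.ndarray, depth_mm: np.ndarray) -> BoundaryTrajectory:
    """Two-segment piecewise-linear fit of boundary depth vs time.

    The breakpoint is chosen by exhaustive search over interior samples
    (each segment keeps >= 3 points, sharing the breakpoint sample),
    minimising the total squared error of two independently fitted lines.
    Slopes are returned in mm/hr.  With fewer than 6 points a single line
    is fitted and flagged.
    """
    t = np.asarray(times_min, dtype=float)
    z = np.asarray(depth_mm, dtype=float)
    keep = np.isfinite(z)
    t, z = t[keep], z[keep]
    censored = np.zeros(t.size, dtype=int)
    if t.size < 6:
        slope, _ = np.polyfit(t, z, 1) if t.size >= 2 else (np.nan, np.nan)
        rate = slope * 60.0
        return BoundaryTrajectory(t, z, censored, rate_fast_mm_per_hr=float(rate),
                                  rate_slow_mm_per_hr=float(rate), single_segment=True)

    def sse_line(ts, zs):
        A = np.column_stack([ts, np.ones_like(ts)])
        coef, res, *_ = np.linalg.lstsq(A, zs, rcond=None)
        r = zs - A @ coef
        return float(r @ r), coef

    best = None
    for i in range(2, t.size - 2):  # breakpoint sample index, >=3 points each side
        s1, c1 = sse_line(t[: i + 1], z[: i + 1])
        s2, c2 = sse_line(t[i:], z[i:])
        total = s1 + s2
        if best is None or total < best[0]:
            best = (total, i, c1, c2)
    _, i, c1, c2 = best
    return BoundaryTrajectory(
        t, z, censored,
        rate_fast_mm_per_hr=float(c1[0] * 60.0),
        rate_slow_mm_per_hr=float(c2[0] * 60.0),
        breakpoint_min=float(t[i]),
    )


def detect_layer_onset(
    times_min: np.ndarray,
    halfwidth_Hz: np.ndarray,
    threshold_frac: float = 0.20,
    persistence: int = 3,
    baseline_points: int = 10,
):
    """Onset of layer separation from reference-resonance broadening.

    Macroscopic layering degrades field homogeneity, broadening the
    concentration-insensitive reference line.  The baseline half-width is
    the median of the first ``baseline_points`` samples; onset is the first
    time the half-width exceeds baseline*(1+threshold_frac) for at least
    ``persistence`` consecutive samples.  Returns the onset time in minutes
    or None (no onset: compatible with an arrested, non-settling state).
    """
    t = np.asarray(times_min, dtype=float)
    w = np.asarray(halfwidth_Hz, dtype=float)
    if t.size < baseline_points:
        raise ValueError(f"need >= {baseline_points} points to establish a baseline")
    base = float(np.median(w[:baseline_points]))
    exceed = w > base * (1.0 + threshold_frac)
    run = 0
    for i, e in enumerate(exceed):
        run = run + 1 if e else 0
        if run >= persistence:
            return float(t[i - persistence + 1])
    return None


def profiles_to_frame(profiles: Sequence[SliceProfile], geometry: SliceGeometry) -> pd.DataFrame:
    """Long-format table (time_min, slice, center_mm, lean_pct, dense_pct)."""
    rows = []
    for p in profiles:
        for k in range(geometry.n_slices):
            rows.append({
                "time_min": p.time_min,
                "slice": k,
                "center_mm": geometry.slice_centers_mm[k],
                "lean_pct": p.lean_pct[k],
                "dense_pct": p.dense_pct[k],
                "usable": bool(p.usable[k]),
            })
    return pd.DataFrame(rows)
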