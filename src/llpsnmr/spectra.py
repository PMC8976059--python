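"""Spectrum and decay-series containers plus ASCII I/O and FID processing.

The package works on frequency-domain 1D spectra exported as two-column
ASCII (ppm, intensity) with a plain-text key:value metadata sidecar, the
way processed spectrometer output is typically exported for downstream
lineshape analysis.  A minimal time-domain path (exponential apodization +
FFT) is provided so synthetic signals can be pushed through the same
processing the real data saw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionMeta",
    "Spectrum1D",
    "DecaySeries",
    "SpectrumParseError",
    "read_spectrum_xy",
    "write_spectrum_xy",
    "ppm_to_hz",
    "hz_to_ppm",
    "process_fid",
]

#: 19F resonance frequency on the instrument modelled throughout (MHz).
DEFAULT_FREQ_19F_MHZ = 470.0


class SpectrumParseError(ValueError):
    """Raised when an ASCII spectrum file cannot be parsed."""


@dataclass
class AcquisitionMeta:
    """Acquisition metadata attached to a spectrum.

    Parameters
    ----------
    spectrometer_freq_19F : float
        19F Larmor frequency in MHz (470 for a 500 MHz instrument).
    time_min : float
        Minutes since the kinetic trigger (temperature jump).
    temperature_C : float
        Sample temperature in degrees Celsius.
    slice_index : int or None
        Index of the spatially-selective slice, or None for bulk detection.
    em_lb_Hz : float
        Exponential line broadening applied during processing, Hz.
    """

    spectrometer_freq_19F: float = DEFAULT_FREQ_19F_MHZ
    time_min: float = 0.0
    temperature_C: float = 25.0
    slice_index: Optional[int] = None
    em_lb_Hz: float = 0.0

    def __post_init__(self) -> None:
        if self.spectrometer_freq_19F <= 0:
            raise ValueError("spectrometer_freq_19F must be positive")
        if self.em_lb_Hz < 0:
            raise ValueError("em_lb_Hz must be non-negative")


@dataclass
class Spectrum1D:
    """A real absorptive 1D spectrum on an ascending ppm axis."""

    axis_ppm: np.ndarray
    intensity: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        self.axis_ppm = np.asarray(self.axis_ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis_ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("axis and intensity must be 1-D arrays")
        if self.axis_ppm.size != self.intensity.size:
            raise ValueError("axis and intensity must have the same length")
        if self.axis_ppm.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.axis_ppm)):
            raise ValueError("axis contains non-finite values")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        diffs = np.diff(self.axis_ppm)
        if np.any(diffs == 0):
            raise ValueError("duplicated ppm values on axis")
        if np.any(diffs < 0):
            # normalise to ascending order
            order = np.argsort(self.axis_ppm)
            self.axis_ppm = self.axis_ppm[order]
            self.intensity = self.intensity[order]
            if np.any(np.diff(self.axis_ppm) <= 0):
                raise ValueError("axis is not strictly monotone")

    def __len__(self) -> int:
        return int(self.axis_ppm.size)

    def crop(self, lo_ppm: float, hi_ppm: float) -> "Spectrum1D":
        """Return the sub-spectrum with lo_ppm <= axis <= hi_ppm."""
        mask = (self.axis_ppm >= lo_ppm) & (self.axis_ppm <= hi_ppm)
        if mask.sum() < 2:
            raise ValueError(f"window [{lo_ppm}, {hi_ppm}] ppm contains <2 points")
        return Spectrum1D(self.axis_ppm[mask], self.intensity[mask], replace(self.meta))

    @property
    def step_ppm(self) -> float:
        return float(np.median(np.diff(self.axis_ppm)))


@dataclass
class DecaySeries:
    """A relaxation or diffusion decay series.

    ``x`` is delay time in seconds for inversion-recovery / CPMG data, or
    gradient strength in T/m for pulsed-field-gradient diffusion data.
    """

    x: np.ndarray
    y: np.ndarray
    kind: str  # inversion_recovery | cpmg | pfg
    big_delta_s: Optional[float] = None  # diffusion time (pfg only)
    little_delta_s: Optional[float] = None  # gradient pulse length (pfg only)

    KINDS = ("inversion_recovery", "cpmg", "pfg")

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}")
        if self.x.size != self.y.size:
            raise ValueError("x and y must have the same length")
        if np.any(self.x < 0) or np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        if self.kind == "pfg":
            if self.big_delta_s is None or self.little_delta_s is None:
                raise ValueError("pfg series needs big_delta_s and little_delta_s")


_META_KEYS = {
    "spectrometer_freq_19F": float,
    "time_min": float,
    "temperature_C": float,
    "slice_index": int,
    "em_lb_Hz": float,
}


def _read_sidecar(path) -> AcquisitionMeta:
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise SpectrumParseError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, val = (s.strip() for s in line.split(":", 1))
        if key not in _META_KEYS:
            continue  # unknown keys are ignored, not fatal
        try:
            kwargs[key] = _META_KEYS[key](val)
        except ValueError as exc:
            raise SpectrumParseError(f"{path}:{lineno}: bad value for {key}: {val!r}") from exc
    return AcquisitionMeta(**kwargs)


def read_spectrum_xy(path, sidecar=None) -> Spectrum1D:
    """Read a two-column ASCII spectrum (ppm, intensity).

    Columns may be whitespace- or comma-delimited; ``#`` starts a comment.
    ``sidecar`` is an optional key:value metadata file; absent keys take
    documented defaults (470 MHz, t=0 min, 25 degC, bulk detection, 0 Hz LB).
    The returned axis is ascending regardless of file order.
    """
    ppm, intens = [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise SpectrumParseError(
                f"{path}:{lineno}: expected 2 numeric columns, got {len(parts)}"
            )
        try:
            ppm.append(float(parts[0]))
            intens.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"{path}:{lineno}: non-numeric value in {raw!r}") from exc
    meta = _read_sidecar(sidecar) if sidecar is not None else AcquisitionMeta()
    return Spectrum1D(np.array(ppm), np.array(intens), meta)


def write_spectrum_xy(spectrum: Spectrum1D, path, sidecar_path=None) -> None:
    """Write a spectrum as full-precision two-column ASCII (+ sidecar)."""
    lines = ["# ppm intensity"]
    for x, y in zip(spectrum.axis_ppm, spectrum.intensity):
        lines.append(f"{float(x)!r} {float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n")
    if sidecar_path is not None:
        m = spectrum.meta
        out = [
            f"spectrometer_freq_19F: {float(m.spectrometer_freq_19F)!r}",
            f"time_min: {float(m.time_min)!r}",
            f"temperature_C: {float(m.temperature_C)!r}",
            f"em_lb_Hz: {float(m.em_lb_Hz)!r}",
        ]
        if m.slice_index is not None:
            out.append(f"slice_index: {m.slice_index}")
        Path(sidecar_path).write_text("\n".join(out) + "\n")


def ppm_to_hz(delta_ppm: float, freq_MHz: float = DEFAULT_FREQ_19F_MHZ) -> float:
    """Convert a ppm offset to Hz at the given spectrometer frequency."""
    if freq_MHz <= 0:
        raise ValueError("freq_MHz must be positive")
    return delta_ppm * freq_MHz


def hz_to_ppm(delta_hz: float, freq_MHz: float = DEFAULT_FREQ_19F_MHZ) -> float:
    """Inverse of :func:`ppm_to_hz`."""
    if freq_MHz <= 0:
        raise ValueError("freq_MHz must be positive")
    return delta_hz / freq_MHz


def process_fid(
    fid: np.ndarray,
    dwell_s: float,
    lb_Hz: float = 0.0,
    freq_MHz: float = DEFAULT_FREQ_19F_MHZ,
    carrier_ppm: float = 0.0,
) -> Spectrum1D:
    """Apodize and Fourier-transform a complex FID into a real spectrum.

    The FID is multiplied by exp(-pi * lb_Hz * t) (exponential multiplication,
    which adds lb_Hz of Lorentzian width), discrete-Fourier-transformed, and
    the real (absorptive) part returned on a ppm axis centred at
    ``carrier_ppm``.  A pure damped exponential of intrinsic FWHM w yields a
    Lorentzian of FWHM w + lb_Hz within the digital resolution.
    """
    if lb_Hz < 0:
        raise ValueError("lb_Hz must be non-negative")
    if dwell_s <= 0:
        raise ValueError("dwell_s must be positive")
    fid = np.asarray(fid, dtype=complex)
    n = fid.size
    t = np.arange(n) * dwell_s
    window = np.exp(-np.pi * lb_Hz * t)
    apodized = fid * window
    apodized = apodized.copy()
    apodized[0] *= 0.5  # half first point: standard DFT convention for one-sided FIDs
    spec = np.fft.fftshift(np.fft.fft(apodized)) * dwell_s
    freqs_hz = np.fft.fftshift(np.fft.fftfreq(n, d=dwell_s))
    axis_ppm = carrier_ppm + freqs_hz / freq_MHz
    meta = AcquisitionMeta(spectrometer_freq_19F=freq_MHz, em_lb_Hz=lb_Hz)
    return Spectrum1D(axis_ppm, spec.real, meta)
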