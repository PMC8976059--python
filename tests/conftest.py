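import numpy as np
import pytest

from llpsnmr.spectra import Spectrum1D, AcquisitionMeta
from llpsnmr.deconv import lorentzian_profile
from llpsnmr.quant import CalibrationModel


FIXTURE_COEFFS = dict(delta0=-77.000, theta_C=0.0025, theta_T=0.010, theta_Y=-0.005)


@pytest.fixture
def calibration():
    """Synthetic fixture calibration: dense (higher C) lies downfield of lean."""
    return CalibrationModel(**FIXTURE_COEFFS)


def make_spectrum(components, lo=-78.5, hi=-75.5, n=2048, sigma=0.0, seed=0,
                  baseline=0.0, freq=470.0):
    """Sum of (center_ppm, fwhm_Hz, area) Lorentzians plus optional noise."""
    axis = np.linspace(lo, hi, n)
    y = np.full(n, float(baseline))
    for c, w, a in components:
        y = y + lorentzian_profile(axis, c, w, a, freq)
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, n)
    return Spectrum1D(axis, y, AcquisitionMeta(spectrometer_freq_19F=freq))


@pytest.fixture
def make_spec():
    return make_spectrum
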