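"""Spectral lineshapes.

The package models IR bands as pseudo-Voigt profiles: a peak-height-normalised
weighted sum of a Gaussian and a Lorentzian of common center and FWHM,

    pV(v) = A * [ eta * G(v) + (1 - eta) * L(v) ],

with ``eta`` the Gaussian fraction.  Peak-height parameterisation is used
throughout (amplitude = absorbance at the band center) because detection
limits and signal-to-noise are naturally expressed in peak OD.
"""

from __future__ import annotations

import numpy as np

FOUR_LN2 = 4.0 * np.log(2.0)


def pseudo_voigt(x, amplitude: float, center: float, fwhm: float, gauss_fraction: float = 0.5):
    """Peak-height-normalised pseudo-Voigt profile."""
    dx2 = np.square(np.asarray(x, dtype=float) - center)
    w2 = fwhm * fwhm
    g = np.exp(-FOUR_LN2 * dx2 / w2)
    lor = 1.0 / (1.0 + 4.0 * dx2 / w2)
    return amplitude * (gauss_fraction * g + (1.0 - gauss_fraction) * lor)


def pseudo_voigt_area(amplitude: float, fwhm: float, gauss_fraction: float = 0.5) -> float:
    """Analytic area of the peak-height pseudo-Voigt.

    Unit-peak Gaussian area = fwhm * sqrt(pi / ln 2) / 2;
    unit-peak Lorentzian area = pi * fwhm / 2.
    """
    ga = 0.5 * np.sqrt(np.pi / np.log(2.0))
    la = 0.5 * np.pi
    return float(amplitude * fwhm * (gauss_fraction * ga + (1.0 - gauss_fraction) * la))
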