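"""Nitrile band location, pseudo-Voigt fitting, and apo/holo shift detection.

Bands are fitted as sums of peak-height pseudo-Voigt profiles plus a local
linear baseline by nonlinear least squares (lmfit); parameter uncertainties
come from the covariance of the converged fit.  Fitting is carried out in a
local coordinate centred on the fit window, which both conditions the problem
and makes the fit exactly equivariant under shifts of the wavenumber origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model, Parameters
from scipy.signal import find_peaks

from .lineshapes import pseudo_voigt, pseudo_voigt_area
from .spectra import Spectrum

__all__ = [
    "BandFit",
    "ShiftResult",
    "detect_peaks",
    "fit_bands",
    "frequency_shift",
    "measure_peak_height",
    "snr",
]

DEFAULT_FIT_HALFWIDTH_CM1 = 25.0


@dataclass
class BandFit:
    """Converged (or flagged) parameters of one fitted band."""

    center_cm1: float
    center_se: float
    fwhm_cm1: float
    fwhm_se: float
    amplitude_od: float
    amplitude_se: float
    gauss_fraction: float
    gauss_fraction_se: float
    area_od_cm1: float
    window: tuple[float, float]
    residual_rms_od: float
    converged: bool
    ambiguous: bool = False
    label: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ShiftResult:
    """Frequency shift between two fitted bands, uncertainty in quadrature."""

    shift_cm1: float
    uncertainty_cm1: float
    variant: str = ""
    condition_a: str = ""
    condition_b: str = ""


def detect_peaks(spec: Spectrum, min_prominence: float,
                 window: tuple[float, float] | None = None) -> list[float]:
    """Local maxima above a prominence threshold, ordered by prominence."""
    mask = np.ones(spec.wavenumber.size, dtype=bool) if window is None \
        else spec.window_mask(*window)
    wn = spec.wavenumber[mask]
    a = spec.absorbance[mask]
    if wn.size < 3:
        return []
    idx, props = find_peaks(a, prominence=min_prominence)
    order = np.argsort(props["prominences"])[::-1]
    return [float(wn[i]) for i in idx[order]]


def _unconverged(window: tuple[float, float], rms: float) -> BandFit:
    nan = float("nan")
    return BandFit(nan, nan, nan, nan, nan, nan, nan, nan, nan,
                   window, rms, converged=False)


def fit_bands(spec: Spectrum,
              n_bands: int = 1,
              init: list[float] | None = None,
              window: tuple[float, float] | None = None,
              fwhm_init: float = 10.0,
              gauss_fraction_init: float = 0.5,
              vary_gauss_fraction: bool = True,
              min_prominence: float | None = None) -> list[BandFit]:
    """Nonlinear least-squares fit of ``n_bands`` pseudo-Voigt profiles.

    Initial centers come from ``init`` or from :func:`detect_peaks`.  A flat
    or peak-free spectrum yields a single flagged (non-converged) result
    rather than a silent failure; asking for more bands than detectable peaks
    emits a warning and fits the surplus components constrained inside the
    window.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    if window is None:
        if init:
            window = (min(init) - DEFAULT_FIT_HALFWIDTH_CM1,
                      max(init) + DEFAULT_FIT_HALFWIDTH_CM1)
        else:
            window = (float(spec.wavenumber[0]), float(spec.wavenumber[-1]))
    mask = spec.window_mask(*window)
    wn = spec.wavenumber[mask]
    a = spec.absorbance[mask]
    if wn.size < 5 * n_bands + 2:
        raise ValueError("fit window contains too few points")

    if init is None:
        if min_prominence is None:
            min_prominence = 3.0 * _robust_noise(a)
        init = detect_peaks(spec, min_prominence, window)
    init = [c for c in init if window[0] <= c <= window[1]]
    if len(init) == 0:
        return [_unconverged(window, float(np.sqrt(np.mean(np.square(a - a.mean())))))]
    ambiguous = len(init) > n_bands
    if len(init) < n_bands:
        warnings.warn(
            f"requested {n_bands} bands but detected only {len(init)} peaks; "
            "surplus components constrained inside the window", UserWarning,
            stacklevel=2,
        )
        # spread surplus components over the window
        extra = np.linspace(window[0], window[1], n_bands - len(init) + 2)[1:-1]
        init = init + [float(c) for c in extra]
    init = init[:n_bands]

    # local coordinate: exact equivariance under wavenumber-origin shifts
    origin = 0.5 * (window[0] + window[1])
    x = wn - origin

    def component(prefix: str) -> Model:
        return Model(pseudo_voigt, prefix=prefix)

    model = component("b0_")
    for i in range(1, n_bands):
        model = model + component(f"b{i}_")

    def baseline(x, b_intercept=0.0, b_slope=0.0):
        return b_intercept + b_slope * x

    model = model + Model(baseline)

    params = Parameters()
    span = window[1] - window[0]
    amp_scale = max(float(np.ptp(a)), 1e-12)
    for i, c in enumerate(init):
        pre = f"b{i}_"
        params.add(pre + "amplitude", value=amp_scale, min=0.0)
        params.add(pre + "center", value=c - origin, min=-span / 2, max=span / 2)
        params.add(pre + "fwhm", value=fwhm_init, min=0.5, max=span)
        params.add(pre + "gauss_fraction", value=gauss_fraction_init, min=0.0, max=1.0,
                   vary=vary_gauss_fraction)
    params.add("b_intercept", value=float(np.median(a)))
    params.add("b_slope", value=0.0)

    result = model.fit(a, params, x=x)
    rms = float(np.sqrt(np.mean(np.square(result.residual))))
    converged = bool(result.success) and result.errorbars

    fits = []
    for i in range(n_bands):
        pre = f"b{i}_"
        p = result.params

        def se(name: str) -> float:
            err = p[pre + name].stderr
            return float(err) if (converged and err is not None) else float("nan")

        amp = float(p[pre + "amplitude"].value)
        fwhm = float(p[pre + "fwhm"].value)
        frac = float(p[pre + "gauss_fraction"].value)
        fits.append(BandFit(
            center_cm1=float(p[pre + "center"].value) + origin,
            center_se=se("center"),
            fwhm_cm1=fwhm,
            fwhm_se=se("fwhm"),
            amplitude_od=amp,
            amplitude_se=se("amplitude"),
            gauss_fraction=frac,
            gauss_fraction_se=se("gauss_fraction"),
            area_od_cm1=pseudo_voigt_area(amp, fwhm, frac),
            window=window,
            residual_rms_od=rms,
            converged=converged,
            ambiguous=ambiguous,
        ))
    fits.sort(key=lambda f: f.center_cm1)
    return fits


def frequency_shift(fit_a: BandFit, fit_b: BandFit,
                    variant: str = "", condition_a: str = "a",
                    condition_b: str = "b") -> ShiftResult:
    """Shift = center_b - center_a with quadrature-propagated uncertainty."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("frequency_shift requires two converged fits")
    return ShiftResult(
        shift_cm1=fit_b.center_cm1 - fit_a.center_cm1,
        uncertainty_cm1=float(np.hypot(fit_a.center_se, fit_b.center_se)),
        variant=variant,
        condition_a=condition_a,
        condition_b=condition_b,
    )


def measure_peak_height(spec: Spectrum, center_cm1: float,
                        fwhm_cm1: float = 10.0, gauss_fraction: float = 0.5,
                        halfwidth_cm1: float = DEFAULT_FIT_HALFWIDTH_CM1) -> float:
    """Amplitude of a known-shape band by linear least squares.

    Fits [profile, 1, (v - center)] to the window.  Unlike the nonlinear fit
    this estimator is exact for noiseless data, remains well defined at zero
    or negative amplitude, and is the default calibration-curve response.
    """
    mask = spec.window_mask(center_cm1 - halfwidth_cm1, center_cm1 + halfwidth_cm1)
    wn = spec.wavenumber[mask]
    if wn.size < 4:
        raise ValueError("window contains too few points")
    profile = pseudo_voigt(wn, 1.0, center_cm1, fwhm_cm1, gauss_fraction)
    design = np.column_stack([profile, np.ones_like(wn), wn - center_cm1])
    coef, *_ = np.linalg.lstsq(design, spec.absorbance[mask], rcond=None)
    return float(coef[0])


def _robust_noise(a: np.ndarray) -> float:
    """Noise SD estimate from the median absolute successive difference."""
    if a.size < 3:
        return 0.0
    d = np.diff(a)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def snr(spec: Spectrum, signal_window: tuple[float, float],
        noise_window: tuple[float, float]) -> float:
    """Peak height in the signal window over detrended RMS in the noise window.

    Windows must be disjoint.  The signal is measured above the straight line
    joining the signal-window edges; the noise RMS is computed after removing
    a linear trend.  Zero noise returns +inf.
    """
    if not (signal_window[1] < noise_window[0] or noise_window[1] < signal_window[0]):
        raise ValueError("signal and noise windows must be disjoint")
    smask = spec.window_mask(*signal_window)
    nmask = spec.window_mask(*noise_window)
    if smask.sum() < 3 or nmask.sum() < 3:
        raise ValueError("windows contain too few points")
    swn, sa = spec.wavenumber[smask], spec.absorbance[smask]
    edge_line = np.interp(swn, [swn[0], swn[-1]], [sa[0], sa[-1]])
    peak = float(np.max(sa - edge_line))
    nwn, na = spec.wavenumber[nmask], spec.absorbance[nmask]
    resid = na - np.polynomial.polynomial.polyval(
        nwn, np.polynomial.polynomial.polyfit(nwn, na, 1))
    rms = float(np.sqrt(np.mean(np.square(resid))))
    if rms == 0.0:
        return float("inf")
    return peak / rms
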