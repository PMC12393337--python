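"""Balanced dual-beam signal processing: voltages to calibrated absorbance.

Pipeline (default order, configurable): phase correction -> gain/baseline
calibration from a blank-blank sweep -> ratio absorbance -> Savitzky-Golay
smoothing -> Fourier low-pass -> polynomial baseline correction.

Absorbance reconstruction
-------------------------
With the reference photodiode responsivity ``1/g`` entering both the monitor
voltage and the balanced subtraction (see :mod:`cnprobe.simulate`), the
sample- and blank-beam intensities are recovered as

    I_sample = v_ref + v_bal        I_blank = g * v_ref

and the decadic absorbance is the log-ratio of beam intensities,

    A(v) = -log10( (v_ref + v_bal) / (g * v_ref) ) - A0(v),

where ``g(v)`` and the residual structure ``A0(v)`` come from an explicit
blank-blank calibration sweep (``g = 1 + v_bal / v_ref`` there).  For a
perfectly balanced pair (g = 1) the ratio reduces to
``(g*v_ref + v_bal) / (g*v_ref)``.  Because the shared source fluctuation
multiplies numerator and denominator alike, it cancels exactly in the ratio —
the quantitative content of balanced detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import firwin, savgol_filter

from .spectra import GridMismatchError, RawSweep, Spectrum, check_same_grid

__all__ = [
    "BalanceCalibration",
    "ProcessingConfig",
    "phase_correct",
    "calibrate_balance",
    "compute_absorbance",
    "sg_filter",
    "fourier_filter",
    "baseline_correct",
    "average_sweeps",
    "single_beam_absorbance",
    "process_sweep",
]

LN10 = np.log(10.0)


class NonPositiveIntensityError(ValueError):
    """Reconstructed beam-intensity ratio is <= 0 somewhere."""


@dataclass
class BalanceCalibration:
    """Per-grid-point detector gain ratio and residual absorbance baseline."""

    wavenumber: np.ndarray
    gain: np.ndarray  # dimensionless g(v) > 0
    baseline_od: np.ndarray  # A0(v), OD

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        self.baseline_od = np.asarray(self.baseline_od, dtype=float)
        if np.any(self.gain <= 0):
            raise ValueError("calibrated gain must be > 0 everywhere")


@dataclass
class ProcessingConfig:
    """Parameters of the standard processing chain.

    ``sg_window``/``fourier_cutoff``/``baseline_anchors`` set to None skip the
    corresponding step.
    """

    phase_deg: float = 0.0
    sg_window: int | None = 11
    sg_order: int = 3
    fourier_cutoff: float | None = 0.25  # fraction of Nyquist in the conjugate domain
    baseline_anchors: Sequence[tuple[float, float]] | None = ((2160.0, 2200.0), (2255.0, 2292.0))
    baseline_order: int = 2
    calibration_smooth_window: int | None = None  # SG window for noisy gain estimates

    @classmethod
    def minimal(cls) -> "ProcessingConfig":
        """Absorbance reconstruction only; no smoothing, filtering or baseline."""
        return cls(sg_window=None, fourier_cutoff=None, baseline_anchors=None)

    def validate(self, n_points: int) -> None:
        if not -180.0 < self.phase_deg <= 180.0:
            raise ValueError("phase must lie in (-180, 180] degrees")
        if self.sg_window is not None:
            if self.sg_window % 2 != 1 or self.sg_window <= self.sg_order:
                raise ValueError("sg_window must be odd and > sg_order")
            if self.sg_window > n_points:
                raise ValueError("sg_window exceeds grid length")
        if self.fourier_cutoff is not None and not 0.0 < self.fourier_cutoff <= 1.0:
            raise ValueError("fourier_cutoff must lie in (0, 1]")


def phase_correct(raw: RawSweep, phase_deg: float) -> RawSweep:
    """Rotate lock-in outputs into the in-phase axis.

    With quadrature data present each channel pair (v, q) is rotated by the
    phase angle; with magnitude-only data the channels are multiplied by
    cos(phase error), the in-phase projection contract.  Identity at 0 deg.
    """
    if not -180.0 < phase_deg <= 180.0:
        raise ValueError("phase must lie in (-180, 180] degrees")
    if phase_deg == 0.0:
        return raw
    theta = np.radians(phase_deg)
    c, s = np.cos(theta), np.sin(theta)
    out = raw.copy()
    if raw.has_quadrature:
        out.v_ref = c * raw.v_ref + s * raw.v_ref_q
        out.v_ref_q = -s * raw.v_ref + c * raw.v_ref_q
        out.v_bal = c * raw.v_bal + s * raw.v_bal_q
        out.v_bal_q = -s * raw.v_bal + c * raw.v_bal_q
    else:
        out.v_ref = c * raw.v_ref
        out.v_bal = c * raw.v_bal
    out.meta["phase_corrected_deg"] = phase_deg
    return out


def calibrate_balance(blank_blank: RawSweep,
                      smooth_window: int | None = None,
                      smooth_order: int = 2) -> BalanceCalibration:
    """Derive the gain ratio g(v) and residual baseline from a blank-blank sweep.

    On a blank-blank acquisition the balanced output is the pure detector
    mismatch, so ``g = 1 + v_bal / v_ref`` pointwise; with noisy input the
    pointwise estimate is Savitzky-Golay smoothed over ``smooth_window``.  The
    residual baseline A0 is whatever absorbance the calibrated reconstruction
    still reports on the calibration sweep itself, so applying the calibration
    back to its own sweep yields |A| = 0 to rounding.
    """
    if np.any(blank_blank.v_ref <= 0):
        raise NonPositiveIntensityError("reference channel non-positive in calibration sweep")
    g = 1.0 + blank_blank.v_bal / blank_blank.v_ref
    if smooth_window is not None:
        g = savgol_filter(g, smooth_window, smooth_order, mode="mirror")
    if np.any(g <= 0):
        raise ValueError("calibrated gain non-positive; calibration sweep unusable")
    ratio = (blank_blank.v_ref + blank_blank.v_bal) / (g * blank_blank.v_ref)
    if np.any(ratio <= 0):
        raise NonPositiveIntensityError("non-positive intensity ratio in calibration sweep")
    baseline = -np.log10(ratio)
    if smooth_window is not None:
        baseline = savgol_filter(baseline, smooth_window, smooth_order, mode="mirror")
    return BalanceCalibration(blank_blank.wavenumber, g, baseline)


def compute_absorbance(raw: RawSweep, cal: BalanceCalibration) -> Spectrum:
    """Ratio-of-beam-intensities absorbance: A = -log10(I_sample / I_blank) - A0."""
    check_same_grid(raw.wavenumber, cal.wavenumber)
    denom = cal.gain * raw.v_ref
    num = raw.v_ref + raw.v_bal
    ratio = num / denom
    bad = ratio <= 0
    if np.any(bad):
        nu = raw.wavenumber[bad][0]
        raise NonPositiveIntensityError(
            f"non-positive beam-intensity ratio at {nu:.2f} cm^-1"
        )
    a = -np.log10(ratio) - cal.baseline_od
    return Spectrum(raw.wavenumber, a, history=[{"step": "compute_absorbance"}],
                    meta=dict(raw.meta))


def sg_filter(spec: Spectrum, window: int, order: int) -> Spectrum:
    """Savitzky-Golay least-squares local polynomial smoothing (mirror edges)."""
    if window % 2 != 1 or window <= order:
        raise ValueError("window must be odd and > order")
    if window > spec.wavenumber.size:
        raise ValueError("window exceeds grid length")
    # 'interp' edge handling keeps the filter exact on polynomials up to
    # the fit order over the whole grid, edges included
    out = savgol_filter(spec.absorbance, window, order, mode="interp")
    return spec.with_absorbance(out, "sg_filter", window=window, order=order)


def fourier_filter(spec: Spectrum, cutoff: float, numtaps: int = 201) -> Spectrum:
    """Low-pass filter in the Fourier-conjugate domain of the wavenumber axis.

    Implemented as a zero-phase windowed-sinc (Hamming) FIR convolution whose
    passband edge is ``cutoff`` as a fraction of the Nyquist frequency of the
    wavenumber grid; endpoints are handled by mirror extension.  cutoff = 1 is
    the identity.  The FIR realisation keeps high-frequency structure (etalon
    fringes) suppressed by > 50 dB without the passband leakage of a sharp
    block-FFT cutoff.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    a = spec.absorbance
    if cutoff == 1.0:
        return spec.with_absorbance(a.copy(), "fourier_filter", cutoff=cutoff)
    numtaps = min(numtaps | 1, 2 * (a.size - 1) + 1)
    taps = firwin(numtaps, cutoff)  # scipy normalises to the Nyquist frequency
    half = numtaps // 2
    ext = np.concatenate([a[half:0:-1], a, a[-2:-half - 2:-1]])
    out = np.convolve(ext, taps, mode="valid")
    return spec.with_absorbance(out, "fourier_filter", cutoff=cutoff)


def baseline_correct(spec: Spectrum,
                     anchors: Sequence[tuple[float, float]],
                     poly_order: int = 2,
                     band_window: tuple[float, float] | None = None) -> Spectrum:
    """Subtract a polynomial fitted through anchor wavenumber windows.

    ``band_window`` (if given) is only used to warn when an anchor overlaps
    the region that will be fitted.
    """
    mask = np.zeros(spec.wavenumber.size, dtype=bool)
    for lo, hi in anchors:
        if band_window is not None and lo <= band_window[1] and hi >= band_window[0]:
            warnings.warn(
                f"baseline anchor ({lo}, {hi}) overlaps the band window {band_window}",
                UserWarning, stacklevel=2,
            )
        mask |= spec.window_mask(lo, hi)
    if mask.sum() <= poly_order:
        raise ValueError("not enough anchor points for the requested polynomial order")
    # fit in a scaled variable for conditioning
    t = (spec.wavenumber - spec.wavenumber.mean()) / 100.0
    coeffs = np.polynomial.polynomial.polyfit(t[mask], spec.absorbance[mask], poly_order)
    fitted = np.polynomial.polynomial.polyval(t, coeffs)
    return spec.with_absorbance(spec.absorbance - fitted, "baseline_correct",
                                anchors=list(map(tuple, anchors)), order=poly_order)


def average_sweeps(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra with standard error SD/sqrt(n)."""
    if len(spectra) == 0:
        raise ValueError("no spectra to average")
    wn = spectra[0].wavenumber
    for s in spectra[1:]:
        check_same_grid(wn, s.wavenumber)
    stack = np.vstack([s.absorbance for s in spectra])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    se = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    hist = list(spectra[0].history) + [{"step": "average_sweeps", "n": n}]
    return Spectrum(wn, mean, se=se, history=hist, meta=dict(spectra[0].meta))


def single_beam_absorbance(sample: RawSweep, blank: RawSweep) -> Spectrum:
    """Reference-channel-only absorbance, for comparison with balanced processing.

    Uses the monitor channel of two separate sweeps, so the (uncorrelated)
    source fluctuations of both acquisitions enter the result — the situation
    balanced detection is designed to avoid.
    """
    check_same_grid(sample.wavenumber, blank.wavenumber)
    if np.any(sample.v_ref <= 0) or np.any(blank.v_ref <= 0):
        raise NonPositiveIntensityError("non-positive reference intensity")
    a = -np.log10(sample.v_ref / blank.v_ref)
    return Spectrum(sample.wavenumber, a,
                    history=[{"step": "single_beam_absorbance"}], meta=dict(sample.meta))


def process_sweep(raw: RawSweep,
                  calibration: RawSweep | BalanceCalibration,
                  config: ProcessingConfig | None = None,
                  band_window: tuple[float, float] | None = None) -> Spectrum:
    """Full chain from a raw sweep (plus its calibration sweep) to a spectrum."""
    if config is None:
        config = ProcessingConfig()
    config.validate(raw.wavenumber.size)
    if isinstance(calibration, RawSweep):
        cal_sweep = phase_correct(calibration, config.phase_deg)
        calibration = calibrate_balance(cal_sweep, config.calibration_smooth_window)
    raw = phase_correct(raw, config.phase_deg)
    spec = compute_absorbance(raw, calibration)
    if config.sg_window is not None:
        spec = sg_filter(spec, config.sg_window, config.sg_order)
    if config.fourier_cutoff is not None:
        spec = fourier_filter(spec, config.fourier_cutoff)
    if config.baseline_anchors is not None:
        spec = baseline_correct(spec, config.baseline_anchors, config.baseline_order,
                                band_window=band_window)
    return spec
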