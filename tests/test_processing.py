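"""Balanced processing: phase, calibration, absorbance, filters, averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cnprobe.fitting import fit_bands
from cnprobe.lineshapes import pseudo_voigt
from cnprobe.processing import (
    BalanceCalibration,
    NonPositiveIntensityError,
    ProcessingConfig,
    average_sweeps,
    baseline_correct,
    calibrate_balance,
    compute_absorbance,
    fourier_filter,
    phase_correct,
    process_sweep,
    sg_filter,
)
from cnprobe.simulate import Band, InstrumentModel, SampleModel, generate_sweep
from cnprobe.spectra import GridMismatchError, RawSweep, Spectrum


def _sweep(n=101, v_ref=1.0, v_bal=0.0, quadrature=False):
    wn = 2000.0 + 0.5 * np.arange(n)
    kw = {}
    if quadrature:
        kw = {"v_ref_q": np.zeros(n), "v_bal_q": np.zeros(n)}
    return RawSweep(wn, np.full(n, v_ref), np.full(n, v_bal), **kw)


# --- phase correction -----------------------------------------------------

def test_phase_zero_is_identity():
    raw = _sweep()
    out = phase_correct(raw, 0.0)
    assert np.array_equal(out.v_ref, raw.v_ref)
    assert np.array_equal(out.v_bal, raw.v_bal)


def test_phase_sixty_degrees_projects_to_half():
    out = phase_correct(_sweep(v_ref=1.0), 60.0)
    assert np.allclose(out.v_ref, 0.5, atol=1e-12)


def test_phase_round_trip_with_quadrature():
    raw = _sweep(v_ref=1.3, v_bal=-0.2, quadrature=True)
    back = phase_correct(phase_correct(raw, 37.5), -37.5)
    assert np.max(np.abs(back.v_ref - raw.v_ref)) < 1e-12
    assert np.max(np.abs(back.v_bal - raw.v_bal)) < 1e-12


def test_phase_validation():
    with pytest.raises(ValueError):
        phase_correct(_sweep(), 181.0)


# --- balance calibration --------------------------------------------------

def test_gain_recovered_from_noiseless_blank_blank():
    inst = InstrumentModel(gain_imbalance=1.05)
    blank = SampleModel()
    pair = generate_sweep(inst, blank, blank, seed=0)
    cal = calibrate_balance(pair.blank_blank)
    assert np.max(np.abs(cal.gain - 1.05)) < 1e-12
    # applying the calibration back to its own sweep gives |A| ~ 0
    spec = compute_absorbance(pair.blank_blank, cal)
    assert np.max(np.abs(spec.absorbance)) < 1e-12


def test_zero_balanced_channel_gives_unit_gain_zero_baseline():
    cal = calibrate_balance(_sweep(v_ref=2.0, v_bal=0.0))
    assert np.allclose(cal.gain, 1.0)
    assert np.allclose(cal.baseline_od, 0.0)


def test_noisy_calibration_smoothed_then_applied_to_clean_blank():
    inst = InstrumentModel(gain_imbalance=1.02, detector_noise_sd=3e-7)
    blank = SampleModel()
    noisy = generate_sweep(inst, blank, blank, seed=5).blank_blank
    cal = calibrate_balance(noisy, smooth_window=151)
    clean = generate_sweep(InstrumentModel(gain_imbalance=1.02), blank, blank,
                           seed=6).blank_blank
    spec = compute_absorbance(clean, cal)
    assert np.max(np.abs(spec.absorbance)) < 1e-6


def test_calibration_rejects_nonpositive_reference():
    bad = _sweep()
    bad.v_ref[3] = -1.0
    with pytest.raises(NonPositiveIntensityError):
        calibrate_balance(bad)


# --- absorbance -----------------------------------------------------------

def test_absorbance_zero_for_balanced_null():
    raw = _sweep(v_ref=2.0, v_bal=0.0)
    cal = BalanceCalibration(raw.wavenumber, np.ones(raw.wavenumber.size),
                             np.zeros(raw.wavenumber.size))
    assert np.allclose(compute_absorbance(raw, cal).absorbance, 0.0)


def test_absorbance_closed_form_ratio():
    """g*v_ref = 2.0 V, v_bal = -0.2 V -> ratio 0.9 -> A = -log10(0.9)."""
    raw = _sweep(v_ref=2.0, v_bal=-0.2)
    cal = BalanceCalibration(raw.wavenumber, np.ones(raw.wavenumber.size),
                             np.zeros(raw.wavenumber.size))
    a = compute_absorbance(raw, cal).absorbance
    assert np.allclose(a, -np.log10(0.9))
    assert a[0] == pytest.approx(0.045757, abs=1e-6)


def test_absorbance_nonpositive_ratio_names_wavenumber():
    raw = _sweep(v_ref=1.0, v_bal=0.0)
    raw.v_bal[10] = -1.5  # ratio -0.5 at the 10th point
    cal = BalanceCalibration(raw.wavenumber, np.ones(raw.wavenumber.size),
                             np.zeros(raw.wavenumber.size))
    with pytest.raises(NonPositiveIntensityError, match="2005.00"):
        compute_absorbance(raw, cal)


def test_absorbance_grid_mismatch():
    raw = _sweep(n=50)
    cal = BalanceCalibration(_sweep(n=60).wavenumber, np.ones(60), np.zeros(60))
    with pytest.raises(GridMismatchError):
        compute_absorbance(raw, cal)


# --- Savitzky-Golay -------------------------------------------------------

def test_sg_preserves_polynomials_up_to_order():
    wn = 2000.0 + 0.5 * np.arange(601)
    quad = 1e-3 + 2e-4 * (wn - 2150.0) + 3e-6 * (wn - 2150.0) ** 2
    out = sg_filter(Spectrum(wn, quad), 11, 2)
    assert np.max(np.abs(out.absorbance - quad)) < 1e-10


def test_sg_noise_reduction_matches_convolution_oracle():
    """Output white-noise SD equals sigma * l2-norm of the SG kernel, the
    kernel being rederived here from the local least-squares design."""
    window, order = 11, 2
    # independent kernel derivation: first row of the local polynomial
    # projection matrix evaluated at the window center
    x = np.arange(-(window // 2), window // 2 + 1, dtype=float)
    design = np.vander(x, order + 1, increasing=True)
    proj = design @ np.linalg.inv(design.T @ design) @ design.T
    kernel = proj[window // 2]
    predicted = np.sqrt(np.sum(kernel ** 2))

    wn = 2000.0 + 0.5 * np.arange(601)
    rng = np.random.default_rng(0)
    sds = []
    for _ in range(150):
        noisy = rng.normal(0.0, 1e-3, wn.size)
        out = sg_filter(Spectrum(wn, noisy), window, order)
        sds.append(out.absorbance[20:-20].std())
    assert np.mean(sds) / (1e-3 * predicted) == pytest.approx(1.0, abs=0.02)


def test_sg_does_not_shift_symmetric_band():
    wn = 2000.0 + 0.5 * np.arange(601)
    band = Spectrum(wn, pseudo_voigt(wn, 1e-2, 2235.0, 10.0, 0.5))
    c0 = fit_bands(band, 1, init=[2235.0], window=(2210, 2260))[0].center_cm1
    c1 = fit_bands(sg_filter(band, 11, 2), 1, init=[2235.0],
                   window=(2210, 2260))[0].center_cm1
    assert abs(c1 - c0) < 0.01


def test_sg_validation():
    wn = 2000.0 + 0.5 * np.arange(101)
    with pytest.raises(ValueError):
        sg_filter(Spectrum(wn, np.zeros(101)), 10, 2)
    with pytest.raises(ValueError):
        sg_filter(Spectrum(wn, np.zeros(101)), 3, 3)


# --- Fourier filter -------------------------------------------------------

def test_fourier_cutoff_one_is_identity():
    wn = 2000.0 + 0.5 * np.arange(601)
    rng = np.random.default_rng(1)
    spec = Spectrum(wn, rng.normal(size=601))
    out = fourier_filter(spec, 1.0)
    assert np.max(np.abs(out.absorbance - spec.absorbance)) < 1e-10


def test_fourier_removes_etalon_fringe_keeps_band():
    wn = 2000.0 + 0.5 * np.arange(601)
    band = pseudo_voigt(wn, 1e-2, 2235.0, 10.0, 0.5)
    fringe = 2e-3 * np.sin(2 * np.pi * wn / 3.0)
    out = fourier_filter(Spectrum(wn, band + fringe), 0.25)
    interior = slice(60, -60)  # away from the mirror-extended edges
    resid = np.abs(out.absorbance - band)[interior]
    assert resid.max() < 0.01 * 2e-3

    only_band = fourier_filter(Spectrum(wn, band), 0.25).absorbance
    area_before = np.trapezoid(band, wn)
    area_after = np.trapezoid(only_band, wn)
    assert abs(area_after - area_before) / area_before < 0.01


def test_fourier_validation():
    wn = 2000.0 + 0.5 * np.arange(101)
    with pytest.raises(ValueError):
        fourier_filter(Spectrum(wn, np.zeros(101)), 0.0)


# --- linearity of all filters (property) ----------------------------------

@given(
    a=st.floats(-3.0, 3.0), b=st.floats(-3.0, 3.0),
    seed=st.integers(0, 2**16),
)
def test_filters_are_linear_operators(a, b, seed):
    wn = 2000.0 + 0.5 * np.arange(301)
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=301), rng.normal(size=301)
    for op in (lambda s: sg_filter(s, 11, 3),
               lambda s: fourier_filter(s, 0.3),
               lambda s: baseline_correct(s, [(2000.0, 2020.0), (2130.0, 2150.0)], 1)):
        combined = op(Spectrum(wn, a * x + b * y)).absorbance
        separate = a * op(Spectrum(wn, x)).absorbance + b * op(Spectrum(wn, y)).absorbance
        assert np.max(np.abs(combined - separate)) < 1e-10


# --- baseline correction --------------------------------------------------

def test_baseline_zero_input_identity():
    wn = 2000.0 + 0.5 * np.arange(601)
    out = baseline_correct(Spectrum(wn, np.zeros(601)),
                           [(2160.0, 2200.0), (2255.0, 2292.0)], 2)
    assert np.max(np.abs(out.absorbance)) < 1e-12


def test_baseline_removes_generated_linear_drift():
    """1e-3 OD per 100 cm^-1 drift from the generator is removed to 1e-6."""
    inst = InstrumentModel()
    sample = SampleModel(baseline_coeffs_od=(0.0, 1e-3), pathlength_um=250.0)
    blank = SampleModel(pathlength_um=250.0)
    pair = generate_sweep(inst, sample, blank, seed=0)
    spec = process_sweep(pair.sample, pair.blank_blank, ProcessingConfig.minimal())
    out = baseline_correct(spec, [(2160.0, 2200.0), (2255.0, 2292.0)], 1)
    assert np.max(np.abs(out.absorbance[out.window_mask(2160, 2292)])) < 1e-6


def test_baseline_leaves_band_center_unchanged():
    wn = 2000.0 + 0.5 * np.arange(601)
    band = pseudo_voigt(wn, 8e-3, 2226.4, 10.0, 0.5)
    drift = 1e-3 * (wn - 2150.0) / 100.0 + 5e-4
    spec = Spectrum(wn, band + drift)
    corrected = baseline_correct(spec, [(2160.0, 2200.0), (2255.0, 2292.0)], 1)
    c0 = fit_bands(spec, 1, init=[2226.4], window=(2201, 2251))[0].center_cm1
    c1 = fit_bands(corrected, 1, init=[2226.4], window=(2201, 2251))[0].center_cm1
    assert abs(c1 - c0) < 0.02
    assert abs(c1 - 2226.4) < 0.02


def test_baseline_warns_when_anchor_overlaps_band():
    wn = 2000.0 + 0.5 * np.arange(601)
    spec = Spectrum(wn, np.zeros(601))
    with pytest.warns(UserWarning, match="overlaps"):
        baseline_correct(spec, [(2200.0, 2240.0)], 1, band_window=(2210.0, 2260.0))


# --- averaging ------------------------------------------------------------

def test_average_identical_spectra():
    wn = 2000.0 + 0.5 * np.arange(101)
    spec = Spectrum(wn, np.linspace(0, 1, 101))
    avg = average_sweeps([spec, spec.copy(), spec.copy()])
    assert np.allclose(avg.absorbance, spec.absorbance)
    assert np.allclose(avg.se, 0.0)


def test_average_standard_error_scaling():
    wn = 2000.0 + 0.5 * np.arange(201)
    rng = np.random.default_rng(2)
    sigma = 1e-3
    specs = [Spectrum(wn, rng.normal(0.0, sigma, 201)) for _ in range(100)]
    avg = average_sweeps(specs)
    assert np.mean(avg.se) == pytest.approx(sigma / 10.0, rel=0.2)


def test_average_reduces_center_scatter_as_sqrt_n():
    """Fitted-center scatter shrinks ~2x going from 4 to 16 averages."""
    wn = 2200.0 + 0.5 * np.arange(121)
    truth = pseudo_voigt(wn, 1e-3, 2230.0, 10.0, 0.5)
    rng = np.random.default_rng(3)

    def center_sd(n_avg, reps=25):
        centers = []
        for _ in range(reps):
            specs = [Spectrum(wn, truth + rng.normal(0.0, 2e-4, wn.size))
                     for _ in range(n_avg)]
            avg = average_sweeps(specs)
            centers.append(fit_bands(avg, 1, init=[2230.0],
                                     window=(2205, 2255))[0].center_cm1)
        return np.std(centers)

    ratio = center_sd(4) / center_sd(16)
    assert 1.3 < ratio < 3.1


def test_average_grid_mismatch():
    a = Spectrum(np.arange(10.0), np.zeros(10))
    b = Spectrum(np.arange(11.0), np.zeros(11))
    with pytest.raises(GridMismatchError):
        average_sweeps([a, b])


# --- history --------------------------------------------------------------

def test_history_appends_one_record_per_step():
    inst = InstrumentModel()
    sample = SampleModel(bands=(Band(2235.0),), concentration_uM=100.0)
    blank = SampleModel()
    pair = generate_sweep(inst, sample, blank, seed=0)
    spec = process_sweep(pair.sample, pair.blank_blank, ProcessingConfig())
    steps = [h["step"] for h in spec.history]
    assert steps == ["compute_absorbance", "sg_filter", "fourier_filter",
                     "baseline_correct"]
    assert spec.history[1]["window"] == 11
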