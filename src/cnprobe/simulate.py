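"""Synthetic instrument, sample, and trajectory generators with known ground truth.

This module stands in for the hardware and for MD engines so that every
downstream stage (balanced processing, band fitting, detection-limit analysis,
field analysis, structure context) is testable end-to-end with no instrument
and no download.

Forward model of the dual-beam instrument
-----------------------------------------
The tunable laser sweeps an ascending wavenumber grid.  At each grid point the
source emits intensity ``P(v) * (1 + f(v))`` where ``P`` is the smooth power
profile and ``f`` is a zero-mean multiplicative fluctuation shared by both
beams (the dominant noise of a quantum cascade laser).  The beam is split into
a sample path (transmission ``T_sample = 10**-A_sample``) and a blank path
(``T_blank``).  The reference photodiode has relative responsivity ``1/g``
with respect to the sample photodiode; its photocurrent is both reported as
the monitor voltage and subtracted electronically to form the balanced output:

    v_ref = (1/g) * P * (1 + f) * T_blank             + detector noise
    v_bal = P * (1 + f) * (T_sample - T_blank / g)    + detector noise

For a perfectly balanced pair (``g = 1``) the balanced channel reduces to the
pure transmission difference and is identically zero for sample == blank.
Because the same responsivity enters both outputs, ``g`` is recoverable from a
blank-blank sweep as ``g = 1 + v_bal / v_ref`` (see
:func:`cnprobe.processing.calibrate_balance`), and the sample-beam intensity
is reconstructed exactly as ``v_ref + v_bal``.

Bands follow Beer-Lambert: peak OD = strength [OD/(mM cm)] x concentration
[mM] x pathlength [cm], on top of the broad water combination band near
2100 cm^-1 and an optional polynomial cellular baseline drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .lineshapes import pseudo_voigt
from .spectra import RawSweep

__all__ = [
    "Band",
    "InstrumentModel",
    "SampleModel",
    "SweepPair",
    "FrequencyFixture",
    "TrajectoryModel",
    "SyntheticTrajectory",
    "generate_sweep",
    "generate_calibration_series",
    "generate_cell_spectrum",
    "generate_trajectory",
    "trajectory_preset",
    "TRAJECTORY_PRESETS",
    "qcl_benzonitrile_preset",
    "ftir_benzonitrile_preset",
    "synthetic_structure_pdb",
]

DEFAULT_START_CM1 = 2000.0
DEFAULT_STOP_CM1 = 2300.0
DEFAULT_STEP_CM1 = 0.5

#: default in-cell probe concentration (uM) and aromatic-nitrile band width (cm^-1)
DEFAULT_CELL_CONCENTRATION_UM = 140.0
DEFAULT_BAND_FWHM_CM1 = 10.0
#: benzonitrile-like peak band strength, OD per mM per cm
DEFAULT_BAND_STRENGTH = 0.22

CN_BOND_LENGTH_A = 1.16  # standard nitrile C#N geometry


def default_power_profile(wavenumber: np.ndarray) -> np.ndarray:
    """Smooth, strictly positive relative QCL power curve over 2000-2300 cm^-1."""
    return 1.0 - 3.0e-6 * np.square(np.asarray(wavenumber, dtype=float) - 2150.0)


@dataclass(frozen=True)
class Band:
    """One absorption band of the sample."""

    center_cm1: float
    fwhm_cm1: float = DEFAULT_BAND_FWHM_CM1
    strength_od_mM_cm: float = DEFAULT_BAND_STRENGTH  # peak OD per mM per cm
    gauss_fraction: float = 0.5

    def validate(self) -> None:
        if self.fwhm_cm1 <= 0:
            raise ValueError("band fwhm must be > 0")
        if not 0.0 <= self.gauss_fraction <= 1.0:
            raise ValueError("gauss_fraction must lie in [0, 1]")
        if self.strength_od_mM_cm < 0:
            raise ValueError("band strength must be >= 0")


@dataclass
class InstrumentModel:
    """Dual-beam laser spectrometer parameters."""

    wavenumber_start: float = DEFAULT_START_CM1
    wavenumber_stop: float = DEFAULT_STOP_CM1
    wavenumber_step: float = DEFAULT_STEP_CM1
    laser_power_profile: Callable[[np.ndarray], np.ndarray] = default_power_profile
    source_fluctuation_sd: float = 0.0  # relative, shared by both channels
    detector_noise_sd: float = 0.0  # volts, independent per channel
    gain_imbalance: float = 1.0
    etalon_amplitude_od: float = 0.0
    etalon_period_cm1: float = 3.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.wavenumber_step <= 0:
            raise ValueError("wavenumber step must be > 0")
        if self.wavenumber_start >= self.wavenumber_stop:
            raise ValueError("wavenumber start must be < stop")
        if self.source_fluctuation_sd < 0 or self.detector_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.gain_imbalance <= 0:
            raise ValueError("gain imbalance must be > 0")
        grid = self.grid()
        if np.any(self.laser_power_profile(grid) <= 0):
            raise ValueError("laser power profile must be strictly positive on the grid")

    def grid(self) -> np.ndarray:
        n = int(round((self.wavenumber_stop - self.wavenumber_start) / self.wavenumber_step)) + 1
        return self.wavenumber_start + self.wavenumber_step * np.arange(n)


@dataclass
class SampleModel:
    """Contents of one liquid/cell transmission cell."""

    bands: Sequence[Band] = ()
    concentration_uM: float = 0.0
    pathlength_um: float = 250.0
    water_band_center_cm1: float = 2100.0
    water_band_od_per_um: float = 0.004  # peak OD per um pathlength
    water_band_fwhm_cm1: float = 160.0
    baseline_coeffs_od: Sequence[float] = ()  # polynomial in (v - 2150)/100

    def validate(self) -> None:
        if self.pathlength_um <= 0:
            raise ValueError("pathlength must be > 0")
        if self.concentration_uM < 0:
            raise ValueError("concentration must be >= 0")
        if self.water_band_od_per_um < 0:
            raise ValueError("water band amplitude must be >= 0")
        for band in self.bands:
            band.validate()

    def band_absorbance(self, wavenumber: np.ndarray) -> np.ndarray:
        """Beer-Lambert absorbance of the solute bands only (OD)."""
        wn = np.asarray(wavenumber, dtype=float)
        a = np.zeros_like(wn)
        conc_mM = self.concentration_uM * 1e-3
        path_cm = self.pathlength_um * 1e-4
        for band in self.bands:
            peak = band.strength_od_mM_cm * conc_mM * path_cm
            a += pseudo_voigt(wn, peak, band.center_cm1, band.fwhm_cm1, band.gauss_fraction)
        return a

    def absorbance(self, wavenumber: np.ndarray) -> np.ndarray:
        """Total single-cell absorbance: bands + water background + drift (OD)."""
        wn = np.asarray(wavenumber, dtype=float)
        a = self.band_absorbance(wn)
        if self.water_band_od_per_um > 0:
            peak = self.water_band_od_per_um * self.pathlength_um
            a = a + pseudo_voigt(wn, peak, self.water_band_center_cm1,
                                 self.water_band_fwhm_cm1, 1.0)
        if len(self.baseline_coeffs_od):
            t = (wn - 2150.0) / 100.0
            a = a + np.polynomial.polynomial.polyval(t, np.asarray(self.baseline_coeffs_od))
        return a


@dataclass
class SweepPair:
    """A sample-cell sweep, its blank-blank calibration sweep, and the truth."""

    sample: RawSweep
    blank_blank: RawSweep
    a_true: np.ndarray  # differential absorbance (sample - blank), OD


def generate_sweep(
    instrument: InstrumentModel,
    sample: SampleModel,
    blank: SampleModel,
    seed: int,
) -> SweepPair:
    """Simulate one dual-channel acquisition plus its blank-blank calibration sweep.

    The two sweeps are taken back to back, so the source fluctuation is drawn
    independently for each, while within a sweep the same realisation reaches
    both detectors (this is what balanced detection cancels).
    """
    instrument.validate()
    sample.validate()
    blank.validate()
    wn = instrument.grid()
    a_s = sample.absorbance(wn)
    if instrument.etalon_amplitude_od > 0:
        a_s = a_s + instrument.etalon_amplitude_od * np.sin(
            2.0 * np.pi * wn / instrument.etalon_period_cm1
        )
    a_b = blank.absorbance(wn)
    t_s = np.power(10.0, -a_s)
    t_b = np.power(10.0, -a_b)
    power = instrument.laser_power_profile(wn)
    g = instrument.gain_imbalance
    rng = np.random.default_rng(seed)

    def one(transmission_sample: np.ndarray, cell_id: str) -> RawSweep:
        f = rng.normal(0.0, instrument.source_fluctuation_sd, wn.size) \
            if instrument.source_fluctuation_sd > 0 else 0.0
        beam = power * (1.0 + f)
        i_ref = beam * t_b / g
        v_ref = i_ref + (rng.normal(0.0, instrument.detector_noise_sd, wn.size)
                         if instrument.detector_noise_sd > 0 else 0.0)
        v_bal = beam * transmission_sample - i_ref
        v_bal = v_bal + (rng.normal(0.0, instrument.detector_noise_sd, wn.size)
                         if instrument.detector_noise_sd > 0 else 0.0)
        return RawSweep(wn, v_ref, v_bal, meta={
            "pathlength_um": sample.pathlength_um,
            "cell_id": cell_id,
            "seed": seed,
            "gain_imbalance": g,
        })

    sweep = one(t_s, "sample")
    cal = one(t_b, "blank_blank")
    return SweepPair(sweep, cal, a_s - a_b)


def generate_calibration_series(
    concentrations_uM: Sequence[float],
    instrument: InstrumentModel,
    sample_template: SampleModel,
    seed: int,
    blank: SampleModel | None = None,
) -> list[SweepPair]:
    """One sweep pair per concentration level, identical noise statistics.

    Band amplitude is strictly proportional to concentration before noise
    (Beer-Lambert linearity of the forward model).
    """
    concentrations = [float(c) for c in concentrations_uM]
    if len(concentrations) < 3:
        raise ValueError("a calibration series needs at least 3 concentration levels")
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be >= 0")
    if blank is None:
        blank = SampleModel(
            bands=(),
            concentration_uM=0.0,
            pathlength_um=sample_template.pathlength_um,
            water_band_center_cm1=sample_template.water_band_center_cm1,
            water_band_od_per_um=sample_template.water_band_od_per_um,
            water_band_fwhm_cm1=sample_template.water_band_fwhm_cm1,
        )
    child_seeds = np.random.SeedSequence(seed).generate_state(len(concentrations))
    out = []
    for conc, s in zip(concentrations, child_seeds):
        level = SampleModel(
            bands=tuple(sample_template.bands),
            concentration_uM=conc,
            pathlength_um=sample_template.pathlength_um,
            water_band_center_cm1=sample_template.water_band_center_cm1,
            water_band_od_per_um=sample_template.water_band_od_per_um,
            water_band_fwhm_cm1=sample_template.water_band_fwhm_cm1,
            baseline_coeffs_od=tuple(sample_template.baseline_coeffs_od),
        )
        out.append(generate_sweep(instrument, level, blank, int(s)))
    return out


# ---------------------------------------------------------------------------
# In-cell frequency fixture and cell-spectrum generator
# ---------------------------------------------------------------------------

class FrequencyFixture:
    """Versioned table of apo band centers and binding-induced shifts (cm^-1).

    The holo center is derived as ``apo + shift`` by construction, so the
    fixture invariant holds exactly.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"variant", "apo_cm1", "shift_cm1"}
        if not required.issubset(table.columns):
            raise ValueError(f"fixture table must have columns {sorted(required)}")
        table = table.copy()
        if "holo_cm1" in table.columns:
            stated = table["holo_cm1"].to_numpy(float)
            derived = table["apo_cm1"].to_numpy(float) + table["shift_cm1"].to_numpy(float)
            if np.max(np.abs(stated - derived)) > 1e-6:
                raise ValueError("fixture holo centers inconsistent with apo + shift")
        table["holo_cm1"] = table["apo_cm1"] + table["shift_cm1"]
        self.table = table.set_index("variant", drop=False)

    @classmethod
    def load_default(cls) -> "FrequencyFixture":
        path = resources.files("cnprobe.data").joinpath("frequency_fixture.csv")
        with resources.as_file(path) as p:
            return cls(pd.read_csv(p))

    @property
    def variants(self) -> list[str]:
        return list(self.table.index)

    def _row(self, variant: str) -> pd.Series:
        if variant not in self.table.index:
            raise KeyError(f"unknown variant {variant!r}; known: {self.variants}")
        return self.table.loc[variant]

    def apo(self, variant: str) -> float:
        return float(self._row(variant)["apo_cm1"])

    def shift(self, variant: str) -> float:
        return float(self._row(variant)["shift_cm1"])

    def holo(self, variant: str) -> float:
        return float(self._row(variant)["holo_cm1"])

    def center(self, variant: str, condition: str) -> float:
        """Band center for a (variant, condition) pair.

        ``no_binding_control`` returns the apo center regardless of
        incubation: a probe whose covalent attachment site is removed does
        not shift (C69A-type behaviour).
        """
        if condition == "apo":
            return self.apo(variant)
        if condition == "holo":
            return self.holo(variant)
        if condition == "no_binding_control":
            return self.apo(variant)
        raise ValueError(f"unknown condition {condition!r}")


#: default differential cellular baseline drift, polynomial in (v-2150)/100, OD
DEFAULT_CELL_DRIFT = (2.0e-4, 3.0e-4, 1.5e-4)


def generate_cell_spectrum(
    variant: str,
    condition: str,
    fixture: FrequencyFixture | None = None,
    snr: float = 20.0,
    seed: int = 0,
    instrument: InstrumentModel | None = None,
    concentration_uM: float = DEFAULT_CELL_CONCENTRATION_UM,
    pathlength_um: float = 250.0,
    fwhm_cm1: float = DEFAULT_BAND_FWHM_CM1,
    gauss_fraction: float = 0.5,
    strength_od_mM_cm: float = DEFAULT_BAND_STRENGTH,
    drift_coeffs_od: Sequence[float] = DEFAULT_CELL_DRIFT,
) -> SweepPair:
    """Synthetic in-cell nitrile measurement for one variant and condition.

    ``snr`` sets the ratio of band peak OD to per-point absorbance noise in
    the fully processed spectrum (including the calibration sweep's noise
    contribution); the required detector noise voltage is derived from the
    blank intensity at the band center.  The blank emulates cells expressing unlabeled protein: same
    water background, no nitrile band; the sample cell additionally carries a
    slow polynomial drift (cellular scatter/composition differences).
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    if fixture is None:
        fixture = FrequencyFixture.load_default()
    center = fixture.center(variant, condition)

    band = Band(center, fwhm_cm1, strength_od_mM_cm, gauss_fraction)
    peak_od = strength_od_mM_cm * (concentration_uM * 1e-3) * (pathlength_um * 1e-4)
    blank = SampleModel(bands=(), pathlength_um=pathlength_um)
    sample = SampleModel(
        bands=(band,),
        concentration_uM=concentration_uM,
        pathlength_um=pathlength_um,
        baseline_coeffs_od=tuple(drift_coeffs_od),
    )
    if instrument is None:
        instrument = InstrumentModel(source_fluctuation_sd=1e-2)
    # intensity at the band center sets the detector noise for the target SNR
    intensity = float(
        instrument.laser_power_profile(np.array([center]))[0]
        * 10.0 ** (-blank.absorbance(np.array([center]))[0])
    )
    sigma_a = peak_od / snr
    instrument = InstrumentModel(
        wavenumber_start=instrument.wavenumber_start,
        wavenumber_stop=instrument.wavenumber_stop,
        wavenumber_step=instrument.wavenumber_step,
        laser_power_profile=instrument.laser_power_profile,
        source_fluctuation_sd=instrument.source_fluctuation_sd,
        detector_noise_sd=sigma_a * np.log(10.0) * intensity / _CAL_NOISE_FACTOR,
        gain_imbalance=instrument.gain_imbalance,
        etalon_amplitude_od=instrument.etalon_amplitude_od,
        etalon_period_cm1=instrument.etalon_period_cm1,
    )
    pair = generate_sweep(instrument, sample, blank, seed)
    pair.sample.meta.update(variant=variant, condition=condition,
                            true_center_cm1=center, true_peak_od=peak_od)
    return pair


# The gain/baseline calibration is itself derived from a noisy blank-blank
# sweep, so the processed absorbance carries the quadrature sum of both
# sweeps' detector noise; per-point noise targets are met by scaling the
# detector voltage noise down by sqrt(2).
_CAL_NOISE_FACTOR = np.sqrt(2.0)


# ---------------------------------------------------------------------------
# Benzonitrile detection-limit presets
# ---------------------------------------------------------------------------

def _response_design_factor(center_cm1: float, fwhm_cm1: float, gauss_fraction: float,
                            step_cm1: float, halfwidth_cm1: float = 25.0) -> float:
    """SD of the linear peak-height estimator per unit per-point absorbance SD.

    The calibration response is the amplitude of a known-shape profile fitted
    together with a local linear baseline by ordinary least squares; this
    returns sqrt([(X^T X)^-1]_00) for that design.
    """
    x = np.arange(-halfwidth_cm1, halfwidth_cm1 + step_cm1 / 2, step_cm1)
    profile = pseudo_voigt(x + center_cm1, 1.0, center_cm1, fwhm_cm1, gauss_fraction)
    design = np.column_stack([profile, np.ones_like(x), x])
    cov = np.linalg.inv(design.T @ design)
    return float(np.sqrt(cov[0, 0]))


def _benzonitrile_preset(pathlength_um: float, response_noise_od: float):
    """Instrument + sample template anchored so LOD = 3.3 * sigma / slope.

    The per-point detector noise is back-solved from the requested
    response-level noise through the exact design factor of the peak-height
    estimator, so the series' ground-truth LOD is known in closed form.
    """
    band = Band(2235.0, DEFAULT_BAND_FWHM_CM1, DEFAULT_BAND_STRENGTH, 0.5)
    template = SampleModel(bands=(band,), pathlength_um=pathlength_um)
    blank = SampleModel(bands=(), pathlength_um=pathlength_um)
    factor = _response_design_factor(band.center_cm1, band.fwhm_cm1,
                                     band.gauss_fraction, DEFAULT_STEP_CM1)
    sigma_a = response_noise_od / factor
    wn0 = np.array([band.center_cm1])
    intensity = float(default_power_profile(wn0)[0]
                      * 10.0 ** (-blank.absorbance(wn0)[0]))
    instrument = InstrumentModel(
        source_fluctuation_sd=1e-2,
        detector_noise_sd=sigma_a * np.log(10.0) * intensity / _CAL_NOISE_FACTOR,
    )
    slope = DEFAULT_BAND_STRENGTH * 1e-3 * pathlength_um * 1e-4  # OD per uM
    truth = {
        "slope_od_per_uM": slope,
        "response_noise_od": response_noise_od,
        "lod_uM": 3.3 * response_noise_od / slope,
        "pathlength_um": pathlength_um,
    }
    return instrument, template, blank, truth


def qcl_benzonitrile_preset():
    """Long-pathlength balanced-laser configuration (250 um spacers)."""
    return _benzonitrile_preset(pathlength_um=250.0, response_noise_od=3.0e-5)


def ftir_benzonitrile_preset():
    """Water-transmission-limited conventional configuration (50 um spacers)."""
    return _benzonitrile_preset(pathlength_um=50.0, response_noise_od=80.0 * 1.1e-6 / 3.3)


# ---------------------------------------------------------------------------
# Two-state probe trajectories
# ---------------------------------------------------------------------------

COULOMB_MV_PER_CM = 1439.96  # k_e * e / A^2 expressed in MV/cm (14.3996 V/A)


@dataclass
class TrajectoryModel:
    """Two-state (hydrogen-bonded / free) probe-environment trajectory model.

    The per-frame environment follows a two-state Markov chain with stationary
    hydrogen-bond occupancy ``hbond_occupancy``; ``hbond_switch_prob`` scales
    the transition rates (1.0 gives uncorrelated frames, appropriate for
    sparsely saved trajectory snapshots).  Per-state mean projected fields are
    anchored by a compensating solvent charge whose position is solved in
    closed form, so the construction ground truth is exact.
    """

    n_frames: int = 10_000
    frame_interval_ps: float = 10.0
    hbond_occupancy: float = 0.5
    hbond_switch_prob: float = 1.0
    cn_bond_length_A: float = CN_BOND_LENGTH_A
    bonded_distance_A: float = 2.9  # N...D heavy-atom distance in the bonded state
    bonded_angle_deg: float = 8.0  # D-H tilt away from the D->N direction
    free_distance_A: float = 6.5  # N...D distance in the free state (> cutoff)
    donor_charge_e: float = -0.834
    hydrogen_charge_e: float = 0.417
    dh_bond_length_A: float = 1.0
    bonded_field_MVcm: float = -60.0  # target state-mean projected field
    free_field_MVcm: float = -20.0
    comp_charge_e: float = 0.8
    comp_polar_deg: float = 35.0
    solvent_n: int = 12
    solvent_charge_e: float = 0.1
    solvent_shell_A: tuple[float, float] = (8.0, 12.0)
    jitter_sd_A: float = 0.08
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.hbond_occupancy <= 1.0:
            raise ValueError("hbond_occupancy must lie in [0, 1]")
        if not 0.0 < self.hbond_switch_prob <= 1.0:
            raise ValueError("hbond_switch_prob must lie in (0, 1]")
        if self.bonded_distance_A >= self.free_distance_A:
            raise ValueError("bonded-state distance must be < free-state distance")
        if self.free_distance_A <= 4.0:
            raise ValueError("free-state distance must exceed the 4.0 A H-bond cutoff")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sd_A < 0:
            raise ValueError("jitter sd must be >= 0")


@dataclass
class SyntheticTrajectory:
    """Frames + charge table + ground-truth labels emitted by the generator."""

    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    elements: list[str]
    charges: pd.DataFrame  # atom_index, charge_e, role
    labels: np.ndarray  # bool per frame, True = hydrogen bonded
    truth: dict
    model: TrajectoryModel

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


def _hand_projected_field(charge_e: float, pos: np.ndarray,
                          r_c: np.ndarray, r_n: np.ndarray) -> float:
    """Independently coded Coulomb arithmetic used only by the generator.

    Bond-projected field (MV/cm) at the C/N atom average from a single point
    charge; kept deliberately separate from the analysis engine so that
    generator anchors and `field_analysis` form a dual route.
    """
    axis = (r_n - r_c) / np.linalg.norm(r_n - r_c)
    total = 0.0
    for p in (r_c, r_n):
        d = p - pos
        total += float(np.dot(d, axis)) / float(np.linalg.norm(d)) ** 3
    return 0.5 * COULOMB_MV_PER_CM * charge_e * total


def _solve_comp_position(needed_MVcm: float, charge_e: float, polar_deg: float,
                         r_c: np.ndarray, r_n: np.ndarray) -> np.ndarray:
    """Place the compensating charge so its projected field equals `needed`.

    Positive charges beyond N on the bond axis give negative projected field;
    a positive requirement is met by placing the charge on the carbon side.
    The radial distance is solved with a bracketing root-finder.
    """
    alpha = np.radians(polar_deg)
    if needed_MVcm < 0:
        origin, direction = r_n, np.array([np.cos(alpha), 0.0, np.sin(alpha)])
    else:
        origin, direction = r_c, np.array([-np.cos(alpha), 0.0, np.sin(alpha)])

    def f(t: float) -> float:
        return _hand_projected_field(charge_e, origin + t * direction, r_c, r_n) - needed_MVcm

    lo, hi = 1.4, 120.0
    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"cannot anchor state field {needed_MVcm:+.1f} MV/cm with a "
            f"{charge_e:+.2f} e compensating charge"
        )
    t = brentq(f, lo, hi, xtol=1e-12)
    return origin + t * direction


def generate_trajectory(model: TrajectoryModel, seed: int | None = None) -> SyntheticTrajectory:
    """Generate a two-state probe trajectory with exact construction truth.

    Atoms: probe C, probe N (excluded from field sums), one hydrogen-bond
    donor heavy atom D with its hydrogen H, one compensating solvent charge,
    and a shell of weak solvent charges.  D/H and the compensating charge
    occupy state-dependent base positions; every non-probe atom receives
    independent Gaussian positional jitter each frame.
    """
    model.validate()
    if seed is None:
        seed = model.rng_seed
    rng = np.random.default_rng(seed)

    r_c = np.zeros(3)
    r_n = np.array([model.cn_bond_length_A, 0.0, 0.0])

    # state-dependent donor geometry: D on the bond axis beyond N, H between
    def donor_positions(distance: float) -> tuple[np.ndarray, np.ndarray]:
        d_pos = r_n + np.array([distance, 0.0, 0.0])
        beta = np.radians(model.bonded_angle_deg)
        toward_n = np.array([-np.cos(beta), 0.0, np.sin(beta)])  # tilted D->H
        h_pos = d_pos + model.dh_bond_length_A * toward_n
        return d_pos, h_pos

    d_b, h_b = donor_positions(model.bonded_distance_A)
    d_f, h_f = donor_positions(model.free_distance_A)

    # static solvent shell (same in both states)
    lo, hi = model.solvent_shell_A
    shell = []
    for i in range(model.solvent_n):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        shell.append(v * rng.uniform(lo, hi))
    shell = np.array(shell).reshape(model.solvent_n, 3)
    shell_q = model.solvent_charge_e * np.where(np.arange(model.solvent_n) % 2 == 0, 1.0, -1.0)

    def static_field(d_pos: np.ndarray, h_pos: np.ndarray) -> float:
        total = _hand_projected_field(model.donor_charge_e, d_pos, r_c, r_n)
        total += _hand_projected_field(model.hydrogen_charge_e, h_pos, r_c, r_n)
        for q, pos in zip(shell_q, shell):
            total += _hand_projected_field(q, pos, r_c, r_n)
        return total

    comp_b = _solve_comp_position(model.bonded_field_MVcm - static_field(d_b, h_b),
                                  model.comp_charge_e, model.comp_polar_deg, r_c, r_n)
    comp_f = _solve_comp_position(model.free_field_MVcm - static_field(d_f, h_f),
                                  model.comp_charge_e, model.comp_polar_deg, r_c, r_n)

    base = {
        True: np.vstack([r_c, r_n, d_b, h_b, comp_b, shell]),
        False: np.vstack([r_c, r_n, d_f, h_f, comp_f, shell]),
    }
    n_atoms = 5 + model.solvent_n

    # two-state Markov chain, initialised from its stationary distribution
    p = model.hbond_occupancy
    s = model.hbond_switch_prob
    labels = np.empty(model.n_frames, dtype=bool)
    labels[0] = rng.random() < p
    if model.n_frames > 1:
        u = rng.random(model.n_frames - 1)
        p_f_to_b = s * p
        p_b_to_f = s * (1.0 - p)
        for i in range(1, model.n_frames):
            if labels[i - 1]:
                labels[i] = u[i - 1] >= p_b_to_f
            else:
                labels[i] = u[i - 1] < p_f_to_b

    coords = np.empty((model.n_frames, n_atoms, 3))
    jitter_mask = np.ones(n_atoms, dtype=bool)
    jitter_mask[:2] = False  # probe atoms define the frame and stay fixed
    for i in range(model.n_frames):
        frame = base[bool(labels[i])].copy()
        if model.jitter_sd_A > 0:
            frame[jitter_mask] += rng.normal(0.0, model.jitter_sd_A,
                                             (int(jitter_mask.sum()), 3))
        coords[i] = frame

    elements = ["C", "N", "O", "H", "O"] + ["O"] * model.solvent_n
    roles = ["probe_C", "probe_N", "donor_D", "donor_H", "solvent"] + \
        ["solvent"] * model.solvent_n
    charges = pd.DataFrame({
        "atom_index": np.arange(n_atoms),
        "charge_e": np.concatenate([
            [0.28, -0.56, model.donor_charge_e, model.hydrogen_charge_e,
             model.comp_charge_e], shell_q,
        ]),
        "role": roles,
    })
    truth = {
        "bonded_field_MVcm": model.bonded_field_MVcm,
        "free_field_MVcm": model.free_field_MVcm,
        "occupancy_nominal": p,
        "occupancy_empirical": float(labels.mean()),
        "mean_field_MVcm": p * model.bonded_field_MVcm + (1 - p) * model.free_field_MVcm,
    }
    return SyntheticTrajectory(coords, elements, charges, labels, truth, model)


def _preset_model(bonded: float, free: float, occupancy: float,
                  n_frames: int) -> TrajectoryModel:
    return TrajectoryModel(
        n_frames=n_frames,
        hbond_occupancy=occupancy,
        bonded_field_MVcm=bonded,
        free_field_MVcm=free,
    )


#: state-field anchors (MV/cm) and occupancies solved so the population-weighted
#: means reproduce the reported replicate-average projected fields
TRAJECTORY_PRESETS: dict[str, dict] = {
    "apo_F92": {"bonded": -85.0, "free": -25.0, "occupancy": 19.0 / 60.0, "mean": -44.0},
    "holo_F92": {"bonded": -85.0, "free": -25.0, "occupancy": 42.0 / 60.0, "mean": -67.0},
    "apo_F96": {"bonded": -45.0, "free": -15.0, "occupancy": 8.0 / 30.0, "mean": -23.0},
    "holo_F96": {"bonded": -45.0, "free": -15.0, "occupancy": 11.0 / 30.0, "mean": -26.0},
}


def trajectory_preset(name: str, n_frames: int = 10_000) -> TrajectoryModel:
    """Named two-state models anchored to the reported mean projected fields."""
    if name not in TRAJECTORY_PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(TRAJECTORY_PRESETS)}")
    p = TRAJECTORY_PRESETS[name]
    return _preset_model(p["bonded"], p["free"], p["occupancy"], n_frames)


# ---------------------------------------------------------------------------
# Synthetic crystal-structure stand-ins
# ---------------------------------------------------------------------------

_RING_NAMES = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]

#: nitrile-environment geometry encoded into each synthetic structure:
#: list of (resname, resseq, atom_name, element, distance from nitrile N, unit direction)
_SYNTHETIC_VARIANTS = {
    # one water donor at 3.2 A; ring-to-ring 15 A
    "F28": {"resseq": 28, "ring_distance_A": 15.0, "contacts": [
        ("HOH", 201, "O", "O", 3.2, (0.5, 0.75, 0.0)),
    ]},
    # hydrophobic pocket: only carbon within 3.5 A; ring-to-ring 10 A
    "F62": {"resseq": 62, "ring_distance_A": 10.0, "contacts": [
        ("LEU", 23, "CD1", "C", 3.4, (0.4, 0.8, 0.2)),
        ("HOH", 202, "O", "O", 4.6, (0.1, -0.9, 0.3)),
    ]},
    # two donors: threonine hydroxyl at 2.9 A and a water at 3.2 A; ring 12 A
    "F92": {"resseq": 92, "ring_distance_A": 12.0, "contacts": [
        ("THR", 90, "OG1", "O", 2.9, (0.6, 0.6, 0.2)),
        ("HOH", 201, "O", "O", 3.2, (0.3, -0.8, 0.4)),
        ("THR", 90, "CB", "C", 3.9, (0.9, 0.4, 0.2)),
    ]},
    # hydrophobic pocket next to the chromophore site; ring-to-ring 5 A
    "F96": {"resseq": 96, "ring_distance_A": 5.0, "contacts": [
        ("VAL", 120, "CG1", "C", 3.4, (0.2, 0.9, -0.1)),
        ("HOH", 203, "O", "O", 5.1, (-0.2, 0.8, 0.5)),
    ]},
}


def _pdb_line(serial: int, name: str, resname: str, chain: str, resseq: int,
              xyz: np.ndarray, element: str, het: bool = False,
              altloc: str = " ", occupancy: float = 1.0) -> str:
    record = "HETATM" if het else "ATOM  "
    pname = name if len(name) == 4 else f" {name:<3}"
    return (f"{record}{serial:5d} {pname}{altloc}{resname:>3} {chain}{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


def synthetic_structure_pdb(variant: str) -> str:
    """PDB text for a SYNTHETIC probe-environment structure (not a deposited model).

    Each structure encodes, by construction, the published contact geometry of
    the corresponding probe site: the nitrile-bearing phenyl ring, the nitrile
    C/N, nearby heavy-atom contacts at exact distances from the nitrile N, and
    a chromophore phenol ring whose centroid sits at the quoted ring-to-ring
    distance.  Used wherever the deposited crystal structures cannot be
    downloaded; distances recovered from these files test the measurement
    code, not the crystallography.
    """
    if variant not in _SYNTHETIC_VARIANTS:
        raise KeyError(f"unknown variant {variant!r}; known: {sorted(_SYNTHETIC_VARIANTS)}")
    spec = _SYNTHETIC_VARIANTS[variant]
    lines = [f"REMARK   1 SYNTHETIC PROBE-ENVIRONMENT MODEL {variant} (not a deposited structure)"]
    serial = 1

    # probe phenyl ring, centroid at origin, in the xy-plane
    ring_r = 1.39
    angles = np.radians(np.arange(6) * 60.0)
    ring = np.column_stack([ring_r * np.cos(angles), ring_r * np.sin(angles),
                            np.zeros(6)])
    for name, pos in zip(_RING_NAMES, ring):
        lines.append(_pdb_line(serial, name, "OCF", "A", spec["resseq"], pos, "C"))
        serial += 1
    # nitrile attached radially at the CG position (ortho convention is
    # immaterial for distance observables)
    radial = np.array([1.0, 0.0, 0.0])
    c_nitrile = radial * (ring_r + 1.43)
    n_nitrile = radial * (ring_r + 1.43 + CN_BOND_LENGTH_A)
    lines.append(_pdb_line(serial, "CAN", "OCF", "A", spec["resseq"], c_nitrile, "C"))
    serial += 1
    lines.append(_pdb_line(serial, "NAN", "OCF", "A", spec["resseq"], n_nitrile, "N"))
    serial += 1

    for resname, resseq, name, element, dist, direction in spec["contacts"]:
        u = np.asarray(direction, dtype=float)
        u /= np.linalg.norm(u)
        pos = n_nitrile + dist * u
        lines.append(_pdb_line(serial, name, resname, "A", resseq, pos, element,
                               het=(resname == "HOH")))
        serial += 1

    # chromophore phenol ring with centroid at the quoted ring-to-ring distance,
    # placed away from the contact cluster
    centroid = np.array([0.0, -spec["ring_distance_A"], 0.0])
    for name, pos in zip(_RING_NAMES, ring + centroid):
        lines.append(_pdb_line(serial, name, "HC4", "A", 169, pos, "C", het=True))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
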