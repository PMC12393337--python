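# Methods

This note documents the models, numerical choices, and limitations behind
`cnprobe`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Balanced dual-beam forward model

One acquisition sweeps an ascending wavenumber grid (default 2000–2300 cm⁻¹
at 0.5 cm⁻¹ steps; the step is chosen to resolve ~10 cm⁻¹ bands).  At each grid point the source
emits `P(ν)(1+f(ν))`, where `P` is a smooth positive power profile and `f` a
zero-mean multiplicative fluctuation **shared by both beams within a sweep**
— the dominant noise of a quantum cascade laser.  Temporal 1/f structure is
collapsed to per-point correlated noise; no noise spectrum is modelled, so
the noise stand-in is calibrated only by the balanced-cancellation property.

The beam splits into a sample path (transmission `T_s = 10^−A_s`) and a
blank path (`T_b`).  The reference photodiode has relative responsivity
`1/g`; its photocurrent is both reported and electronically subtracted:

    v_ref = (1/g)·P(1+f)·T_b + n_ref
    v_bal = P(1+f)·T_s − (1/g)·P(1+f)·T_b + n_bal

with independent Gaussian detector noise per channel.  Modelling the gain
imbalance inside the subtraction (rather than in the monitor tap alone) is
what makes `g` *identifiable*: on a blank–blank sweep `v_bal/v_ref = g − 1`
pointwise, so `calibrate_balance` recovers `g = 1 + v_bal/v_ref` exactly in
the noiseless limit, Savitzky–Golay-smoothed otherwise.  For a perfectly
balanced pair (`g = 1`, the default) the model reduces to
`v_bal = P(1+f)(T_s − T_b)`, identically zero for sample ≡ blank.

Absorbance is the decadic log-ratio of reconstructed beam intensities,

    A(ν) = −log₁₀( (v_ref + v_bal) / (g·v_ref) ) − A₀(ν),

where `A₀` is the residual absorbance the calibrated reconstruction still
reports on the calibration sweep itself (hence exactly zero when applied back
to it).  The shared fluctuation multiplies numerator and denominator alike
and cancels exactly — the quantitative content of balanced detection.  With
detector noise present, the calibration sweep contributes a second,
independent copy of the absorbance noise through `g` and `A₀`; the
generators account for this √2 factor when targeting a per-point
absorbance-noise level (e.g. the `snr` argument of `generate_cell_spectrum`).

Samples follow Beer–Lambert: band peak OD = strength [OD mM⁻¹ cm⁻¹] ×
concentration [mM] × pathlength [cm], on top of a broad water combination
band near 2100 cm⁻¹ (Gaussian, amplitude proportional to pathlength,
default 0.004 OD/µm) and an optional polynomial drift.  Defaults: in-cell
probe concentration 140 µM, band FWHM 10 cm⁻¹, band strength
0.22 OD mM⁻¹ cm⁻¹ (a benzonitrile-like aromatic nitrile), pathlengths
selectable across the 50–250 µm spacer range.

## Processing chain

Default order: phase correction → calibration → absorbance →
Savitzky–Golay → conjugate-domain low-pass → polynomial baseline; each step
appends one record to the spectrum's history.  Choices:

- **Phase correction**: with quadrature data, a true rotation of the
  (in-phase, quadrature) pair (invertible); with magnitude-only data, the
  cos(phase-error) projection contract.
- **Savitzky–Golay**: `interp` edge handling, so the filter is exact on
  polynomials up to the fit order over the *whole* grid.
- **"Fourier" low-pass**: zero-phase windowed-sinc (Hamming) FIR convolution,
  cutoff expressed as a fraction of the grid Nyquist frequency, mirror-
  extended endpoints.  The FIR realisation suppresses etalon-fringe
  frequencies by > 50 dB without the passband leakage a sharp block-FFT
  cutoff exhibits on finite records.  Within half the kernel width
  (≈ 50 points) of the grid ends, edge transients remain — band regions
  are kept central.
- **Baseline**: polynomial through anchor windows (defaults 2160–2200 and
  2255–2292 cm⁻¹, excluding the nitrile region), fitted in a scaled variable
  for conditioning; a warning is emitted if an anchor overlaps a declared
  band window.
- **Filtering vs fitting**: the binding assay fits bands on the *unsmoothed*
  reconstruction.  Smoothing before a least-squares profile fit correlates
  the noise and makes covariance-based uncertainties overconfident (shift
  coverage drops from ~93% to ~50% in the suite's coverage test if the
  default filters are applied first).  The filters exist for presentation
  and for fringe suppression, not as fit preprocessing.

Whether the original acquisition software filtered voltages or absorbance is
not specified anywhere; this package filters absorbance, configurably.

## Band fitting and shifts

Bands are modelled as peak-height pseudo-Voigt profiles (weighted
Gaussian/Lorentzian sum, Gaussian fraction free in [0,1], default ½;
Gaussian and Lorentzian are the degenerate settings) plus a local linear
baseline, fitted by nonlinear least squares (lmfit) in a window of ±25 cm⁻¹
around the detected candidate.  Fitting is done in a local coordinate
centred on the window, which conditions the problem and makes the fit
exactly equivariant under shifts of the wavenumber origin.  A single
component is fitted by default (hot bands / Fermi resonances are not
modelled).  Uncertainties come from the converged fit's covariance
(bootstrap deliberately omitted for speed); non-convergence and peak-free
windows are flagged, never silent; when two candidates fall in one window
the more prominent is kept and the result is marked ambiguous.  Shifts are
`center_b − center_a` with quadrature-propagated uncertainty.

For calibration series the response is the amplitude of a *known-shape*
profile fitted with a local linear baseline by linear least squares: exact
on noiseless data, well-defined at zero/negative amplitude (blank levels),
and the default LOD response metric (peak height; area optional via the
analytic pseudo-Voigt area).

## Detection limits

`LOD = factor · σ_resid / slope` with factor 3.3 (3.0 selectable, always
recorded); σ_resid uses an n−2 denominator.  The published experimental
LODs (18 µM at 250 µm; 80 µM at 50 µm water-limited) are not derivable from
first principles — they depend on real instrument noise — so the two
instrument presets are *calibrated stand-ins*: pathlength and band strength
fix the slope, and the response-level noise is back-solved from the quoted
LOD through the exact design factor of the peak-height estimator.  The
acceptance script then recomputes the LODs end-to-end from 200 fresh
synthetic series per preset; agreement tests the estimator chain, not the
instrument physics.  At fixed absorbance noise the Beer–Lambert slope is
proportional to pathlength, giving the analytic 5.0× prediction for
50 → 250 µm; the measured fold (≈ 4.4 with both presets anchored) is the
"approximately five-fold" regime.

## Two-state trajectories and projected fields

The trajectory generator emulates the probe's two-population electrostatic
behaviour, not molecular dynamics: a probe C≡N (bond fixed at 1.16 Å, a
standard nitrile geometry) with a hydrogen-bond donor (O, TIP3P-like
charges −0.834/+0.417 e) whose position switches between a bonded pose
(N···D = 2.9 Å on-axis, D–H tilted 8° from D→N) and a free pose (6.5 Å,
beyond the cutoff), following a two-state Markov chain initialised from its
stationary distribution (occupancy unbiased at finite n).  The default
switch scale of 1 gives uncorrelated frames, appropriate for sparsely saved
snapshots; smaller values yield persistent states.  All non-probe atoms
receive per-frame Gaussian jitter (0.08 Å), and a shell of weak solvent
charges adds structure to the field distribution.

Per-state mean projected fields are *anchored*: a compensating solvent
charge's position is solved in closed form (independently coded Coulomb
arithmetic, bracketing root-finder) so that the noiseless state field equals
the preset target.  The four presets (state means −85/−25 MV/cm for F92,
−45/−15 for F96) have occupancies 19/60, 42/60, 8/30 and 11/30 chosen so the
population-weighted means equal −44, −67, −23 and −26 MV/cm respectively —
the replicate-averaged values the polarizable-MD analysis reports.  These
are generator anchors, not reproduced physics: the engine is a point-charge
Coulomb sum (no induced dipoles or multipoles, no periodic images, probe's
own residue excluded), with k_e·e/Å² = 14.3996 V/Å = 1439.96 MV/cm.

The projected field averages the field vectors at the carbon and the
nitrogen and projects on the C→N unit vector (bond-midpoint evaluation
available behind a flag; which convention the original field calculations
used is not recoverable).  Sign convention: a positive charge beyond N on
the axis gives a negative projected field, so hydrogen-bond donors at the
nitrile produce negative fields.

Hydrogen bonds are assigned geometrically: heavy-atom N···D ≤ 4.0 Å and
angle(D→H, D→N) ≤ 30°, both inclusive (with a 10⁻⁹ rounding guard).  The
angle vertex is configurable (`donor`, the default, or `hydrogen`) because
the prose definition of a "donor–acceptor–hydrogen" angle is ambiguous; the
convention used is recorded in every summary.  Analyses are
replicate-aware: the aggregate field is the mean of replicate means
(default 4 replicates, emulating 4 × 25 ns runs sampled at 10 ps).

## Structure context

PDB files are parsed with gemmi; alternate locations resolve to the highest
occupancy, ties to altloc 'A'.  Crystal structures lack hydrogens, so this
module reports heavy-atom N/O contacts to the nitrile nitrogen within a
cutoff (default 3.5 Å) — potential donors, not full H-bond assignments —
and centroid distances between the probe phenyl and chromophore phenol
rings (≥ 5 of the named ring atoms required; name map configurable).  The
deposited structures cannot be bundled or fetched in an offline run, so the
repository ships *synthetic* reference structures, programmatically built to
encode the published contact geometry of each site (two donors at
2.9/3.2 Å for F92, one water at 3.2 Å for F28, carbon-only environments for
F62/F96, ring separations 15/12/10/5 Å).  Tests against them verify the
measurement code; chain selection defaults to 'A' and "~" distances are
accepted within ±1 Å.

## What the synthetic data do and do not show

The generators share the Beer–Lambert/pseudo-Voigt band model with the
fitting code, carry Gaussian noise, perfectly correlated source fluctuation,
and geometrically clean two-state donors.  Passing tests therefore
demonstrate that the processing, fitting, LOD, field and structure code
recover known ground truth under realistic magnitudes — they do not
demonstrate instrument physics, real cellular backgrounds (scatter,
overlapping absorbers), force-field accuracy, or lineshape theory (observed
field distributions broader than experimental linewidths are out of scope).
Problem sizes used throughout (20 seeds per spectral recovery, 200
calibration series, 10⁴ frames per trajectory) were chosen so every
statistical tolerance is several standard errors wide.

## Known limitations

- No time-domain lock-in demodulation or interferogram processing; sweeps
  begin at demodulated per-wavenumber voltages.
- The FIR low-pass leaves edge transients within half a kernel width of the
  grid ends.
- Covariance-based uncertainties are mildly optimistic once baseline
  correction is applied (empirical shift coverage ≈ 93% at nominal 95%).
- The LOD residual-SD estimate carries the usual chi-distribution bias at
  few degrees of freedom (≈ 6% low at 6 levels); the acceptance test
  accounts for it analytically.
- No Stark-tuning-rate conversion between fields and frequencies is
  attempted (the calibration constant is probe- and method-specific).
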