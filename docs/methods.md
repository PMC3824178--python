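# Methods

This note documents the models implemented in `vepcasl`, the default
parameter values, and the numerical and design choices that are the package's
own rather than forced by the underlying physics.

## Signal model

### Tissue kinetic model

The perfusion-difference (ΔM) signal of labeled blood delivered to tissue
follows the single-compartment general kinetic model for a continuous-labeling
bolus of duration τ arriving at the bolus arrival time Δt (BAT):

- t < Δt: ΔM = 0
- Δt ≤ t < Δt + τ (inflow):
  ΔM(t) = 2 M0b f T1' e^(−Δt/T1b) (1 − e^(−(t−Δt)/T1'))
- t ≥ Δt + τ (clearance):
  ΔM(t) = 2 M0b f T1' e^(−Δt/T1b) (1 − e^(−τ/T1')) e^(−(t−Δt−τ)/T1')

with f = CBF/6000 s⁻¹ (CBF in mL/100 g/min), T1b the blood T1 (1.6 s at 3 T)
and T1' the apparent tissue relaxation time. We use the simplest variant
T1' = T1 tissue (1.3 s for gray matter), i.e. labeled water exchanges into
tissue on arrival; the outflow correction is negligible at these delays. The
closed form is verified in the test suite against direct numerical
integration of dM/dt = f·c(t) − M/T1' to 10⁻⁶.

The brain/blood partition coefficient is deliberately not folded into the
model: calibration divides by an effective *blood* magnetization M0b
(see Calibration), so fitted amplitudes are CBF·M0b directly.

### Macrovascular component

Labeled blood transiting a voxel inside large vessels is modeled as a boxcar
of width τ starting at the arterial arrival time Δta (default Δt − 0.3 s,
clipped at 0), with amplitude 2 M0b·aBV·e^(−t/T1b), where aBV is the arterial
blood volume fraction. It is optional in fitting (`include_macrovascular`)
and shrinks to zero under its zero-mean prior when absent from the data.

### Acquisition timing

A voxel in slice k is read at t = τ + PLD + k·Δt_slice (sequential readout,
Δt_slice = 45.2 ms). Defaults: τ = 1.4 s, six PLDs 0.25–1.5 s, 24 slices,
96 volumes per acquisition.

## Vessel encoding and decoding

Each acquisition cycle modulates the labeling efficiency sinusoidally across
the labeling plane, giving each artery a weight in [−1 (tag), +1 (control)].
A cycle set forms the encoding matrix A (cycles × [4 arteries + static]);
measured volumes are y = A x with x holding half the per-artery ΔM (the
package reports components on the control-minus-tag scale, 2× the raw
solution) plus the static signal.

The standard 8-cycle scheme (non-selective pair, left–right pair,
anterior–posterior pair, diagonal pair) tags and controls every artery
exactly four times; its matrix has mutually orthogonal columns of norm² 8.
Consequences, proved analytically from the pseudo-inverse and verified by
Monte-Carlo in the tests:

- per-artery decoded variance under i.i.d. cycle noise σ² is σ²/8 (raw
  scale) — identical to a matched-duration tag/control acquisition;
- decoded components are uncorrelated;
- the summed four-artery (non-selective-equivalent) image has 4× the
  per-component variance, i.e. half the SNR of plain PCASL.

The diagonal cycle pair cannot be built by a half-period offset (the two
diagonal midpoints of a rectangle coincide); instead the modulation
periodicity is exploited: along the direction at angle atan(a/3b) from x
(a, b the rectangle half-width/half-height) with period 4a·cos θ/3, one
diagonal pair sits a full period apart (both tagged) while the other lands
half a period away (both controlled). With the default rectangular geometry
this reproduces the ideal ±1 matrix exactly.

Two decoders:

- **Matrix inversion** (`decode_matrix_inversion`): pseudo-inverse
  least squares; unbiased, noise as above.
- **MAP classification** (`decode_map`): each voxel is assumed fed by at
  most two arteries. For every class (static only, one artery + static, one
  artery pair + static) the linear sub-model with zero-mean Gaussian
  amplitude priors has a closed-form marginal likelihood, evaluated jointly
  over PLDs via an eigendecomposition identity; the highest-evidence class
  wins (uniform class prior) and amplitudes are re-estimated as the posterior
  mean within it, zeroing non-feeding arteries. Prior scales are relative to
  the data RMS (amplitude 10×, static 100× — effectively weak) so the
  evidence is insensitive to signal units.

**Noise variance for the evidence** is estimated per voxel from the
residuals of the full-rank least-squares fit across all cycles and PLDs
(3 degrees of freedom per PLD with 8 cycles and 5 unknowns). The
control/tag-only pair cannot be used for this: per PLD it is exactly fitted
by the static+perfusion sub-model, leaving zero residual degrees of freedom.

**Vessel-position offset** (`optimize_vessel_offset`): a grid search over a
global in-plane translation (default ±10 mm, 1 mm steps) maximizing the
summed MAP evidence on a signal-ranked voxel subsample, to absorb subject
motion between vessel planning and acquisition. With the ideal rectangular
geometry every vessel sits at a modulation extremum, making the matrix even
in the offset; the shift is then identified up to a global sign, which is
irrelevant because both signs give the identical encoding matrix.

## Model fitting

Per-voxel maximum a posteriori fitting with Gaussian priors: CBF 0 ± 10⁶
(effectively flat, non-negative), BAT 1.3 ± 0.5 s (informative; the source of
the small upward BAT bias at low SNR), aBV 0 ± 0.05. For a fixed BAT the
model is linear in CBF, so single-component fits reduce to a one-dimensional
bounded search over BAT ∈ [0.1, 3.0] s with the closed-form profiled
amplitude, multi-started on the grid {0.5, 1.0, 1.5, 2.0} s plus a full-range
polish (ties break toward the smaller BAT). Multi-component and
macrovascular fits use bounded L-BFGS with the same multi-start strategy.

Uncertainties come from the Laplace approximation: the inverse numerical
Hessian of the negative log posterior at the mode. The noise variance is
either supplied (`noise_sd`, used by the simulation study where it is known
by construction) or initialized from first differences of the curve and
refined from fit residuals (up to 3 passes).

Vessel-decoded data are fitted per artery, one independent single-component
fit per decoded row; non-feeding arteries shrink to zero.

## Calibration

1. **Receive sensitivity**: ratio of head-coil to body-coil calibration
   images (body coil assumed uniform), masked-smoothed with a 1-voxel
   Gaussian and clamped away from zero. A wider kernel (e.g. 2 voxels)
   visibly flattens the bias peak over the ventricles and biases M0 by ~4%,
   hence the 1-voxel default.
2. **CSF reference**: M0_CSF = mean signal in the eroded ventricle mask /
   [(1 − e^(−TR/T1csf)) e^(−TE/T2*csf)] with T1csf = 4.3 s, T2*csf = 750 ms,
   TR = 6 s, TE = 14 ms. Then
   M0b = M0_CSF · 0.87 (blood/CSF proton density) · e^(−TE/T2*b) (T2*b =
   50 ms) · 1.05 (brain density g/mL) · 0.88 (labeling efficiency).
   If erosion empties the mask (tiny phantoms) the uneroded mask is used
   with a warning.
3. Calibrated CBF = fitted amplitude / M0b; variances divide by M0b².

## Background suppression

A presaturation of the imaging region at the start of labeling plus two
global inversions between the end of the labeling train and the readout,
timed so tissues with T1 = T1_opt and 2·T1_opt are exactly nulled at the
first-slice readout. Mz follows closed-form T1 recovery between events; the
solver parameterizes the two times through a logistic map (guaranteeing
τ < t1 < t2 < readout), runs multi-started least squares, and raises if the
best residual exceeds 10⁻⁹ (infeasible request). `max_t1opt` finds the
largest feasible T1_opt per PLD by a descending feasibility scan plus
bisection — the feasible region is an interior interval, since too-short
T1_opt pushes the second inversion into the readout dead time. The resulting
maxima (0.081/0.173/0.387/0.50/0.50 s for PLDs 0.25/0.5/1.0/1.25/1.5 s,
capped at 0.5 s) independently reproduce the protocol table used in
`BSUP_T1OPT_BY_PLD` (0.080/0.170/0.390/0.50/0.50).

## Labeling-efficiency Bloch simulation

Spins move at constant velocity through the labeling plane under a train of
Gaussian RF pulses (600 µs duration, 1 ms spacing, ±3σ truncation) with
6 mT/m gradient during pulses and a refocusing gradient between them chosen
so the mean gradient is 0.8 mT/m. Tag cycles use constant RF phase
(flow-driven adiabatic inversion); control cycles alternate the phase by π.
Integration uses exact axis-angle rotations at 1 µs sub-steps during pulses
and a single exact z-rotation per inter-pulse gap (numba-compiled). The
per-velocity efficiency α(v) = (Mz_control − Mz_tag)/2 is averaged over a
flux-weighted laminar distribution p(v) = 2v/v_max², v_max = 2·30 cm/s, with
Gauss–Legendre quadrature (16 nodes in the acceptance script; α changes by
<10⁻³ between 12 and 16 nodes or between 1 and 0.5 µs steps).

The per-pulse RF amplitude is a free protocol choice; 20° per pulse sits on
the efficiency plateau and gives α ≈ 0.872, with the 15–25° sweep spanning
≈ 0.72–0.93 and bracketing the nominal 0.88. Relaxation during labeling is
off by default (efficiency is defined at the labeling plane).

## Two-artery accuracy simulation

One voxel fed by two arteries: BAT₁ = 1 s fixed, BAT₂ swept 0.5–2.0 s in
0.1 s steps, total CBF 60 split 1:4…4:1, 50 noise realizations per cell.
SNR regimes (high 250, low 30) are defined on the perfusion image averaged
over all repeats and PLDs (GM mean over background sd); the per-PLD noise sd
is therefore σ_avg·√(n_PLD). The same absolute noise applies to the
non-selective signal and to *each* decoded component — the SNR-parity
property of the 8-cycle matrix shown above — so the vessel-encoded arm is
simulated directly as per-artery signal plus noise at that level instead of
synthesizing and decoding 8 cycles per repeat (identical statistics, much
faster). Fits use the known noise sd. Summaries: worst-case mean
underestimation over the grid, and the per-split error onset (smallest
|BAT₂ − BAT₁| with mean error negative and exceeding twice its standard
error).

At high SNR the non-selective fit underestimates total CBF by up to ~37%
(worst at split 1:4 with BAT₂ = 2 s), with onset near a 0.25 s arrival-time
difference, while the vessel-encoded fit stays within ±2%. At low SNR a
small positive bias (~+2%) appears near equal arrival times, driven by the
informative BAT prior.

## Digital phantom

Schematic ellipsoidal head with GM/WM/CSF partial volumes, four vascular
territories from a nearest-artery partition (seeded jitter of territory
centers), mixed-supply bands near territory boundaries (two arteries with a
configurable split and arrival offset), smooth within-territory BAT growth
(0.9→1.4 s), optional arterial-blood-volume hotspots, a smooth receive-coil
bias, and a ventricle mask. The synthetic acquisition multiplies encoding
weights into per-artery ΔM fields, adds the background-suppressed static
tissue (solved inversion timings per PLD, slice-dependent readout), applies
the coil bias and adds Gaussian noise. The `snr` argument is defined on the
PCASL-equivalent perfusion image at the shared 96-volume budget, so the
summed vessel-decoded image shows SNR/2. The phantom emulates acquisition
physics, not anatomy: no motion, no distortion, Gaussian noise, and perfectly
known masks (registration/segmentation are out of scope).

## Problem sizes and runtime

Chosen so the full test suite runs on one CPU in well under 25 minutes:
the full two-artery grid (16 BAT values × 5 splits × 50 repeats,
high SNR) takes ~2 minutes using the profiled single-component fit;
Bloch quadratures use 6–16 velocity nodes; end-to-end phantom tests fit a
random subsample of a few hundred gray-matter voxels (the voxelwise fit is
~20 voxels/s; whole-brain runs simply take minutes, not hours).
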