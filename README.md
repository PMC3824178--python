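# vepcasl

Per-artery cerebral blood flow (CBF) quantification from multi-delay
vessel-encoded pseudocontinuous arterial spin labeling (VEPCASL) MRI —
kinetic modeling, vessel decoding, Bayesian fitting, absolute calibration,
Bloch simulations, a digital phantom, and an end-to-end synthetic pipeline.

## The problem

Arterial spin labeling measures perfusion by magnetically labeling arterial
blood water and imaging its delivery to tissue. Standard pseudocontinuous ASL
(PCASL) yields a single *total* perfusion map; it cannot say which of the
four brain-feeding arteries (right/left internal carotid, right/left
vertebral) supplies a voxel. Vessel-encoded PCASL modulates the labeling
sinusoidally across the labeling plane over a set of encoding cycles so each
artery is tagged or controlled in a known pattern, and a linear decoding step
separates the per-artery signals — at no SNR cost relative to a
matched-duration PCASL scan.

Separating arteries matters for accuracy, not just for vascular-territory
maps: when a voxel receives blood from two arteries with different bolus
arrival times (BAT), a single-component fit to the summed signal can
underestimate total CBF by up to ~37%, because the late-arriving component is
nearly invisible at short post-labeling delays. Fitting each decoded artery
separately removes this bias.

## The model

Tissue signal follows the single-compartment general kinetic model for a
continuous-labeling bolus of duration τ (= 1.4 s) sampled at six
post-labeling delays (0.25–1.5 s), with ΔM(t) ∝ 2 M0b f T1′ e^(−Δt/T1b) and
the usual inflow/clearance phases; fitting is maximum a posteriori with
Gaussian priors (CBF effectively flat, BAT 1.3 ± 0.5 s) and Laplace
uncertainties. Decoding is either plain least squares or a Bayesian MAP
classifier that assigns each voxel to at most two feeding arteries.
Calibration divides by an effective blood magnetization M0b derived from a
CSF reference with receive-coil sensitivity correction. See
[docs/methods.md](docs/methods.md) for the full model, defaults, and design
decisions.

## Worked example

Phantom → 8-cycle synthetic acquisition at SNR 30 → MAP decoding →
sensitivity correction → CSF calibration → per-artery kinetic fits
(`examples/06_full_pipeline.py`):

```text
calibrated M0_b: 0.6112 (truth 0.6076)
median GM total CBF: 57.2 mL/100g/min (truth 57.0, error +0.4%)
  RICA: median CBF in its territory  33.3 (truth  29.9)
  LICA: median CBF in its territory  53.6 (truth  55.1)
  RVA: median CBF in its territory  50.6 (truth  49.7)
  LVA: median CBF in its territory  56.7 (truth  57.2)
```

Why vessel encoding matters for accuracy
(`examples/02_two_artery_accuracy.py`, mean % error of total CBF, high SNR):

```text
method      PCASL  VEPCASL
ratio bat2
1:1   2.0   -28.1      1.3
1:4   2.0   -37.4      1.2
4:1   2.0   -11.7     -0.6
```

Bloch-simulated labeling efficiency (`examples/03_labeling_efficiency.py`):

```text
flow-averaged labeling efficiency alpha = 0.868 (nominal protocol value: 0.88)
```

The other examples demonstrate the kinetic model shapes, background
suppression timing, and the MI-vs-MAP decoders; each is a short narrative
script that prints its results.

A thin CLI wraps the same library calls:

```bash
vepcasl simulate --help        # two-artery accuracy grid
vepcasl label-efficiency       # Bloch simulation
vepcasl bsup-timing            # background-suppression solver
vepcasl run --small OUTDIR     # full synthetic pipeline
```

## Layout

- `src/vepcasl/` — the library (kinetic model, encoding/decoding, Bloch
  simulations, fitting, calibration, phantom, comparison statistics,
  pipeline, CLI)
- `examples/` — narrative scripts, one per capability
- `tests/` — unit, property-based and acceptance tests
- `docs/methods.md` — methods note: models, defaults, numerical choices
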