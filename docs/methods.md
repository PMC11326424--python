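# Methods

This note documents the models, parameters, numerical choices and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem and model

The segmentation target is a dynamic (2D+time) first-pass perfusion series
of one short-axis cardiac slice: an H×W×T intensity volume in which a
contrast bolus transits the right-ventricular pool, then the LV cavity,
then the myocardium. Each pixel belongs to exactly one of three classes —
background (0), LV myocardium (1), bloodpool (2).

**Sliding-patch analysis.** The series is decomposed into overlapping
space-time patches (spatial windows × all frames). A single network maps a
patch's T frames (stacked as input channels) to a per-pixel 3-class
softmax. Per-pixel class probabilities are arithmetic means over covering
patches; the mask is the per-pixel argmax with ties broken toward the
lower class code. Grids clamp the final window flush with the border, so
coverage is complete without padding or fabricated intensities; interior
pixels are covered by more patches than corners whenever stride < patch,
which concentrates sampling on the centred heart ROI.

**Uncertainty.** The U-map is the per-pixel *population* standard
deviation (divisor N) of the covering patches' myocardium probabilities.
With probabilities in [0, 1] this lies in [0, 0.5], the supremum attained
only by half-zeros/half-ones coverage patterns; the population convention
is what makes the 0.5 bound exact (the sample convention would exceed it on
two-point patterns). Upp = ‖U‖²_F / N_myo, with the Frobenius sum over the
whole analysis crop and N_myo the predicted myocardial pixel count. An
empty prediction (N_myo = 0) is assigned Upp = +∞ so that vacuous
certainty can never win selection.

**Pool and selection.** The pool repeats one training procedure with
different seeded initialisations and keeps, per run, up to k checkpoints
whose full-image validation Dice (myocardium class, through the inference
path) reaches the gate. When more epochs qualify than slots, checkpoints
are taken evenly spaced over the qualifying epochs (earliest and latest
included) to maximise intra-run diversity. The data-adaptive regime runs
every member on a test series and keeps the minimal-Upp solution (ties by
manifest order); the established regime fixes the single member with the
highest validation Dice (ties by run seed, then checkpoint epoch). The
alternative selection score — total U-map energy without the 1/N_myo
normalisation — is available behind `selection_metric="total_energy"`.

## Network and optimiser

The patch network is a deliberately small two-level U-Net written directly
in numpy: two 3×3 conv+ReLU pairs per encoder level with 2×2 max pooling,
a single bottleneck conv, nearest-neighbour upsampling with skip
concatenation on the decoder path, and a 1×1 softmax head; He
initialisation from a per-model seed; categorical cross-entropy; Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Convolutions are same-padded im2col
matrix products; the backward pass is hand-derived and verified against
central finite differences (relative error ~1e-6 in the tests). Patch
extents must be divisible by 4 (two pooling levels). Everything about a
model is reproducible from its seed; pools are reproducible from the base
seed because each run's init seed and augmentation stream derive from
`SeedSequence([base_seed, run_index])`.

## Problem-size profiles

Two configuration presets exist; they differ only in scale:

| | desk (default, used by the test suite) | full |
| --- | --- | --- |
| analysis grid | 64 × 64 × 16 | 128 × 128 × 30 |
| patch / train stride / infer stride | 32 / 16 / 8 | 64 / 32 / 16 |
| pool | 2 runs × 3 checkpoints | 5 runs × 10 checkpoints |
| U-Net base width | 8 | 8 |
| epochs / lr / batch | 24 / 3e-3 / 16 | 60 / 1e-3 / 8 |

The inference stride is a quarter of the patch size — the dense-overlap
reading of "combined back with an overlap of one-fourth patch size": a
quarter-patch *stride* gives the many-fold overlap (a pixel inside up to
(patch/stride)² = 16 patches) that makes the U-map informative, whereas a
quarter-patch *overlap* (stride = ¾ patch) would cover most pixels only
once or twice. Both readings are available through
`TrainConfig.infer_stride`. The Dice gate stays at 0.87 in both profiles;
on desk-scale phantoms runs reach it within a few epochs, so gating
primarily filters pre-convergence snapshots.

## Phantom generator

The generator emulates the *structure* the analysis relies on, not
calibrated physiology:

* **Geometry.** A bloodpool disk (cavity radius r), a concentric
  myocardial ring (thickness w), and an optional RV crescent (a displaced
  disk clipped 1 px clear of the epicardium, labelled bloodpool), centred
  in the frame; the config enforces r + w < image/2.
* **Kinetics.** Each tissue follows a gamma-variate bolus curve
  A·((t−t₀)/αβ)^α·exp(α−(t−t₀)/β) on top of a small pre-contrast
  baseline, parameterised so the peak equals A at t₀ + αβ. Sampler
  defaults order the peaks RV → LV cavity → myocardium, the three wash-in
  stages of a first pass.
* **Corruptions.** Perfusion defects are angular myocardial sectors whose
  enhancement amplitude is multiplied by a severity factor in [0, 1);
  coil shading is a multiplicative field of 2–4 broad signed Gaussian
  bumps; noise is additive Gaussian (at magnitude-image SNRs relevant
  here the Rician/Gaussian distinction is immaterial for segmentation);
  residual motion-correction error is emulated by rigid in-plane
  translation of randomly chosen frames (bilinear, edge-replicated),
  leaving the mask on the reference geometry.
* **Populations.** `internal_sampler` draws moderate geometry/kinetics/
  noise variation (defect prevalence 0.3); `shifted_sampler` emulates a
  change of acquisition platform by raising noise (σ 0.03–0.05 vs
  0.01–0.02) and shading (0.2–0.4 vs 0–0.2), shrinking and thinning the
  ring, and delaying/brightening myocardial enhancement (+0.15 peak
  amplitude); its defect distribution equals the internal one — the shift
  is in acquisition-like properties, not pathology prevalence.

What the phantom does **not** reproduce: partial-volume blur (tissue
interfaces are sharp to the pixel), through-plane and cardiac-phase
motion, k-space/acquisition artefacts, calibrated signal-to-concentration
physics, anatomical variability beyond concentric geometry. Passing tests
therefore demonstrate correctness of the machinery and direction-level
behaviour of the selection scheme under controlled shift — not clinical
performance.

## Preprocessing and augmentation choices

* Spatial resampling: bicubic for intensities, nearest-neighbour for
  labels (label codes are never interpolated). Crops are half-open
  windows centred (pixel-centre convention) on a *provided* heart centre;
  phantoms carry theirs natively, real data must supply one.
* Temporal resampling: PCHIP (shape-preserving piecewise cubic) onto a
  uniform grid spanning the input time range — piecewise-cubic without
  overshoot outside the intensity range.
* Normalisation: one min-max per 2D+time series (not per frame), applied
  after cropping so the ROI defines the dynamic range; constant crops are
  a hard error.
* Augmentation defaults (rotation ±15°, shear ±8°, translation ±8 px,
  scale 0.9–1.1, γ 0.7–1.4, noise σ ≤ 0.05, bias amplitude ≤ 30%) are
  label-preserving at the analysis scale; affine draws with near-zero
  determinant are resampled. Augmentation is applied on the fly per epoch
  so different runs see different streams — a deliberate source of pool
  diversity alongside initialisation.

## Evaluation choices

* Dice is defined 1.0 for two empty sets, 0.0 when exactly one is empty.
* HD95 is the *undirected* form: max of the two directed 95th-percentile
  nearest-boundary distances, boundaries being class pixels whose
  4-neighbourhood leaves the class (image borders count), in physical mm.
  An empty side returns +∞ with a warning.
* Failed segmentation: (i) bloodpool inside the filled myocardial
  outline but outside its single largest enclosed cavity; (ii) the
  myocardium (components < 5 px discarded) is not one 8-connected
  component enclosing exactly one cavity, where enclosed holes < 5 px are
  ignored — the criterion targets contour-level defects a visual rater
  would flag, and pixel-scale pinholes in an otherwise perfect ring are
  not that. Criterion (ii) is topological rather than segment-bookkeeping:
  it reproduces noncontiguous-contour failures without needing
  RV-insertion landmarks.
* The comparison driver reports mean ± sd Dice and HD95, failure rates,
  unpaired two-tailed t-tests on Dice and Fisher's exact test on failure
  counts per dataset. At phantom scale these statistics are reported for
  completeness; conclusions drawn in the tests are directional only.

## Known limitations

* Upp rewards solutions whose errors are *consistent* across overlapping
  patches: a member that confidently over-segments can attain low Upp both
  by adding no disagreement and by enlarging the N_myo denominator. With
  sharp-edged phantoms and a small (2×3) desk pool this occasionally makes
  minimal-Upp selection prefer a slightly worse late checkpoint; the
  effect of data-adaptive selection under shift is therefore evaluated
  directionally, and parity on internal-style data is the expected
  outcome whenever the best-on-validation member remains near the
  per-case optimum.
* The under-trained error from checkpoint gating advises either more
  epochs or a lower gate; the gate is relative to task difficulty.
* The CNN engine supports exactly the fixed two-level topology; it is an
  engine for this package, not a general framework.
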