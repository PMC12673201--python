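# Methods

## Problem and model

The package classifies 21×21×21-voxel patches (volumes of interest, VOIs) of
whole-heart coronary MR angiography (CMRA) as containing vs. not containing a
significant coronary stenosis, defined as a ≥50% reduction of luminal
diameter. On CMRA a significant stenosis appears as a focal drop in the
signal-intensity profile along the bright coronary lumen, so the classifier
is a small 3D convolutional network whose attention is explicitly
concentrated at the patch center, where the annotated lesion sits.

The architecture is two feature-extracting blocks with a fixed weighting
layer between them:

    VOI 21³ ─ conv(3³, C₁=16) ─ BN ─ ReLU ─ maxpool(2,2, ceil) → 11³
           ─ ⊙ Gaussian weight G(σ = 0.75 voxels, peak 1)      → 11³
           ─ conv(3³, C₂=32) ─ BN ─ ReLU ─ maxpool(2,2, ceil)  → 6³
           ─ flatten ─ FC(2) ─ softmax → (p_no_stenosis, p_stenosis)

The weighting layer multiplies every channel of the block-1 output
elementwise (Hadamard product) by G[v] = exp(−‖v − c‖²/(2σ²)), a
center-peaked Gaussian over the 11³ map. The spatial contract 21 → 11 → 6
pins the pooling dialect: only ceil-mode pooling with size 2 / stride 2
produces these sides (floor mode would give 10 and 5), and the
`NetworkConfig` constructor enforces it.

Choices the architecture description leaves open, fixed here and exposed in
`NetworkConfig`:

* channel counts 16/32 and 3³ kernels with same-padding — the smallest
  conventional choice for a two-block 3D CNN;
* σ = 0.75 is interpreted in voxel units on the 11³ map. This reading is
  debatable (it could be in units of map half-width or on a normalized
  grid) and materially changes the layer's receptive emphasis, so it is a
  plain config field;
* the weighting sits between the blocks, i.e. on the post-pooling 11³ maps;
* the Gaussian weight is fixed, not learned, and shared across channels;
* initialization: He-uniform conv/FC weights, zero biases, identity batch
  norm, all drawn from a seeded generator.

### NumPy implementation

The network, including backpropagation, is implemented directly on NumPy
arrays: convolution via an im2col built from one contiguous slice-copy per
kernel offset, ceil-mode pooling via −∞ right-padding and an 8-way argmax,
and standard batch-norm forward/backward. At this scale (28 226 learnable
parameters, batches of four 21³ patches) a training step costs ~50 ms on one
CPU core, and every analytic gradient is verified against central finite
differences in the test suite (1e−4 relative on sampled coordinates). SGD
arithmetic runs in float32 by default (`TrainConfig.dtype`), the usual CNN
convention; float64 is available and is what the gradient-check tests use.
One consequence worth knowing: a convolution bias followed by batch
normalization has an exactly zero loss gradient in training mode (BN removes
additive constants), so those biases simply stay at their initialization.

## Training

Loss is the weighted cross-entropy error
WCEE = −(1/n) Σᵢ wᵢ ⟨tᵢ, log yᵢ⟩, with wᵢ the weight of example i's true
class. Class weights default to "auto": inverse class frequency normalized
so the two weights average to 1 (w_k = n/(2 n_k)), computed on the training
set the loss actually sees — i.e. after positive augmentation, per fold.
This is the standard remedy at the ~9% stenosis prevalence the data model
assumes; fixed weights can be supplied instead. Probabilities are clamped at
1e−12 inside the log (clamps are logged) so the loss stays finite.

Optimization: SGD with momentum 0.9, batch size 4, learning rate 1e−4, at
most 50 epochs, seeded shuffling each epoch, last short batch kept. Early
stopping monitors the validation WCEE with patience 5 and restores the
best-validation parameters; the criterion is strict improvement, no minimum
delta. Patience and the metric are configurable since conventions differ.

Cross-validation is patient-level and stenosis-balanced: patients are sorted
by descending positive-segment count (ties shuffled by seed) and assigned
greedily to the fold with the fewest positives (then fewest segments). The
residual positive-count spread between folds is bounded by the largest
single patient's positive count — balance cannot be finer than patient
granularity. Rotation r of the four splits tests on fold r, validates on
fold (r+1) mod 4 and trains on the other two; the validation-fold convention
is this package's choice. VOIs with significant stenosis in the *training*
folds are augmented by one 90° rotation about each axis (×4, counterclockwise
seen from the positive axis end); validation and test folds are never
augmented, and augmented copies inherit their parent's patient, so they can
never cross a fold boundary.

## Data handling

VOIs are extracted centered on annotation voxels (0-based indices
throughout). Annotations within 10 voxels of a volume face are handled by
edge-replication padding with a recorded warning (strict rejection is
available); synthetic annotations can legitimately fall near borders.
Signal is normalized by dividing by the patient's mean volume intensity —
taken literally over all voxels including background; a body-mask option
exists but is off by default. Normalization is therefore scale-equivariant:
a global intensity rescale of a patient's volume leaves its VOIs unchanged.
Inclusion filtering drops stented and CMRA-invisible segments before
anything else and is idempotent.

## Synthetic phantom cohort

No CMRA dataset is deposited, so the package ships a generator whose output
has the statistical and geometric structure the classifier assumes: bright
tubes (lumen 300, background 60 a.u.) of radius 3 voxels on separated lanes
along z in 72³ volumes, mildly curved (quadratic in-plane bend ≤ 2 voxels —
real coronary tortuosity is irrelevant at 21³ patch scale), Gaussian-blurred
(σ = 0.6) with additive Gaussian noise (σ = 8; Rician magnitude noise
available). Positive segments get a focal radius reduction drawn from
[0.5, 1.0] (diameter reduction ≥ 50% *defines* the positive class; the truth
label is recomputed from the drawn fraction), shaped as a raised-cosine bump
of ±4 voxels along the tube and centered at the annotation; negatives carry
a mild (< 25%) irregularity and are annotated at a uniform point on the
centerline — the placement of negative annotations is this module's own
convention. Patients differ by a multiplicative intensity scale
~N(1, 0.05²), so patient-mean normalization is exercised non-trivially.
Defaults describe the cohort used by the end-to-end tests: 60 patients ×
12 segments, 10% expected prevalence.

What the phantoms do **not** emulate: cardiac/respiratory motion, coil
sensitivity profiles, k-space artifacts, vessel branching, plaque signal,
neighboring anatomy. Passing end-to-end tests therefore show that the
pipeline is wired correctly and can recover a focal-narrowing signal at
realistic contrast and noise — not that the classifier reaches any
particular accuracy on clinical CMRA.

The fixture generator reproduces a published dataset's bookkeeping exactly:
from 1034 ICA-visible segments, excluding 28 stented and 55 CMRA-invisible
leaves 951, of which 84 (8.8%) are stenotic; stenotic grades follow the
37:40:7 split over the 50–69/70–99/100% bins and retained negatives the
852:15 split over 0–24/25–49%.

## Evaluation

Conventions on discrete scores are pinned so results are exactly
reproducible: the decision rule is score > threshold (ties at the threshold
count negative); AUC is the Mann–Whitney pairwise estimate with ties ½,
identical to the trapezoidal area under the empirical ROC; the Youden point
maximizes J = sensitivity + specificity − 1 with ties broken toward the
lowest threshold (screening favors sensitivity). By default the Youden
threshold is taken on pooled out-of-fold scores; per-fold thresholds can be
computed by running the evaluator per fold.

The DeLong test for paired AUCs uses placement values: z = (AUC_A −
AUC_B)/√var(diff) with the variance assembled from placement-value
covariances; identical score sets give z = 0, p = 1 with a warning rather
than a 0/0. Group (reader-averaged) comparisons report the arithmetic mean
of per-reader AUCs and a vertically averaged ROC (mean sensitivity on a
common false-positive-rate grid); how a published average-reader comparison
maps onto the two-curve DeLong test is ambiguous, so the package exposes
per-case mean ratings as one defensible input but does not assert it as the
only reading.

Observer-study case selection draws the requested numbers per class (default
40+40) stratified over score deciles within each class, and re-draws
(seeded, capped at 10 000) until the subset AUC is within a tolerance
(default 0.02) of the full-set AUC, returning the best draw if the cap is
hit.

## Problem sizes and numerical notes

The end-to-end acceptance test runs the full four-fold CV on the default
60-patient cohort (~720 segments); with early stopping this takes on the
order of ten minutes on one CPU core. The reproducibility test uses a
reduced cohort (8 patients, 3 epochs) because bit-identity under a fixed
seed is independent of problem size. Determinism guarantees: phantom
volumes, fold assignment, training trajectories and eval-mode forward passes
are all pure functions of their seeds; checkpoints reload bit-identically.

Known limitations: no GPU path; no multi-class stenosis grading; no
multi-reader multi-case variance model (Obuchowski–Rockette) for the
observer machinery; phantom realism as described above.
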