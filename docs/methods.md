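# Methods

This note records the models, parameter choices and numerical conventions
behind `csfseg`, and what the synthetic experiments do and do not establish.

## Problem and pipeline

The clinical quantity is ventricular CSF volume on cranial CT and its change
between two examinations of the same hydrocephalic patient. The pipeline is:
per-slice preprocessing → 2D segmentation network → per-voxel argmax mask →
2.5D slice-consistency pass → voxel-count volumetry. Inference is strictly
2D (axial slice by slice); the only 3D information enters through the
postprocessing pass and through per-exam evaluation.

## Preprocessing

HU values are clipped to a window `(low, high) = (−100, 100)` and mapped
linearly to integers 0–255; the window is configurable (it was chosen
empirically for CSF/brain contrast and is wide enough to keep both tissues
off the saturation ends). Rounding is half-away-from-zero throughout the
8-bit stage, so HU 0 maps to 128.

Histogram equalization uses the classic 256-bin integer lookup
`h(v) = round((cdf(v) − cdf_min) / (N − cdf_min) · 255)` applied **per
slice**. Two numerical facts worth knowing:

- a constant slice (zero denominator) is returned unchanged;
- the map preserves rank order always, and is exactly idempotent for images
  of ≤ 256 pixels; for larger images re-application can drift by at most one
  gray level when value collisions at the lowest occupied bin shift
  `cdf_min`. The tests assert exact idempotence at 16×16 and the ≤1-level
  bound at realistic sizes.

The equalized slice is replicated onto three identical channels and scaled
to [0, 1]. Optional ImageNet-style per-channel normalization exists only for
use with externally trained weights and is off by default.

## Network

Encoder: ResNet basic-block layout with configurable per-stage block counts;
`(3, 4, 6, 3)` with 64 base channels reproduces the ResNet34 geometry at
512×512. Decoder: one stage per encoder stride, each built from a 1×1
convolution into 4× channels initialized with ICNR followed by a ×2 pixel
shuffle, concatenation of the matching encoder skip, and a 3×3
conv–batchnorm–ReLU fusion. ICNR repeats a He-initialized sub-kernel over
each group of `scale²` output channels, which makes pixel-shuffle output
equal nearest-neighbour upsampling at initialization — the anti-checkerboard
property asserted per block in the tests.

Self-attention (one block, in the decoder stage going from stride 16 to 8,
a placement we fix since the architecture description leaves it open): three
1×1 projections (queries/keys at C/8, values at C), row-softmax attention,
and a scalar gain γ initialized to 0 so the block starts as an exact
identity. Decoder widths halve per stage, mirroring the encoder; the head is
a 1×1 convolution with per-pixel softmax.

Everything runs on a small numpy reverse-mode autodiff core
(`csfseg.nn`): im2col convolutions, max-pooling, batch normalization
(running statistics, momentum 0.1), pixel shuffle, batched matmul/softmax.
There is no GPU path; determinism is bit-exact for a fixed seed. Pretrained
encoder weights are an optional load hook (`pretrained_weights_path`), never
a dependency: default initialization is He-normal, since downloading
ImageNet weights is not assumed possible.

### Profiles

| profile | input | blocks | base channels | intended use |
|---|---|---|---|---|
| full | 512×512 | (3,4,6,3) | 64 | documents the full-scale architecture |
| desk | 64×64 | (1,1,1,1) | 16 | all automated tests and CPU experiments |

## Training

Generalized dice loss with class weights `w_l = 1/((Σ_n r_ln)² + ε)` over
both classes (background included), ε = 1e-7 in numerator and denominator —
a perfect prediction scores exactly 0, an absent class gets a finite weight.
Batches pool slices uniformly across all training exams (no slice
balancing). Optimizer is Adam (β₂ = 0.999) with decoupled weight decay
(default 1e-7). The 1cycle policy interpolates cosine-wise from
`max_lr/25` up to `max_lr` over the first 30 % of steps and down to
`max_lr/10⁴` afterwards, with momentum (β₁) running 0.95→0.85→0.95 in
antiphase.

Defaults follow the full-scale recipe: `max_lr = 1e-4`, 4 epochs, batch 10.
That rate belongs to fine-tuning a pretrained encoder; training the desk
profile **from scratch** in the ~80 steps that 8 phantom exams × 4 epochs
provide needs a higher peak, and the desk override uses `max_lr = 1e-2`
(swept over 3e-3–2e-2 during development for convergence on the phantom
task; the choice is a property of the small from-scratch regime, not of the
method). Epochs, batch size, schedule and loss are identical across
profiles.

Augmentation (the recipe names it without detail, so defaults are declared
here): horizontal flip p = 0.5, rotation ±10°, isotropic zoom 0.9–1.1,
identical transforms on image and mask, nearest-neighbour resampling for the
mask so it stays binary.

Half precision: the `mixed_precision` flag emulates reduced activation
precision by quantizing batch inputs through float16; master weights,
gradients and all reported numbers are full precision. It is off in every
test.

## Postprocessing

One pass over interior slices; each pixel is relabelled only when both axial
neighbours contradict it, neighbours always read from the *original*
prediction (the pure form is order-independent; whether the original authors
iterated is unstated, and one pass is what is described). First and last
slices are copied unchanged; volumes with ≤ 2 slices pass through.

## Evaluation

Metrics are computed per exam over all voxels (CSF positive). Conventions:
any metric with a zero denominator is 1.0 when prediction and reference are
both empty of CSF, else 0.0 (the clinical data never hits this; phantom
tests can). Volumetric similarity is `1 − |FP−FN|/(2TP+FP+FN)`.

Fold construction: patients with multiple exams are placed first, in
decreasing exam count, on pairwise distinct folds; single-exam patients are
then shuffled (seeded) and each goes to the fold currently lightest in
exams. Fold means weight exams equally ("averaged between patients in the
fold" is ambiguous when a fold's patients have unequal exam counts; exam
counts are what the fold tables balance, so exams are the unit). The spread
across folds is the sample standard deviation (n−1), 0.0 for a single fold.

## Phantoms

The generator emulates the features the pipeline actually relies on:

- head = ellipsoidal bone shell (1000±50 HU) around brain tissue (30±5 HU),
  air outside (−1000 HU);
- CSF compartment = union of 2–6 ellipsoidal lobes, lateralized
  asymmetrically (one side scaled by 1±asymmetry), joined to the brain
  center by thin channels; CSF at 7±4 HU — inside the preprocessing window,
  separable from brain but overlapping under noise;
- lobe radii are rescaled under bounded retries until the CSF fraction of
  brain volume lands in a configured band (default 3–12 %), erroring if the
  geometry cannot reach it;
- cohorts give designated patients follow-up exams whose CSF volume grows by
  a configured relative drift (default 20 %), emulating progression;
- per-tissue Gaussian HU noise; everything deterministic per seed.

Two deliberate regularizations reflect scale, not convenience: structure z
radii are floored at ≈3 slices (capped on very coarse grids), and the
ground-truth compartment is made a fixed point of the slice-consistency
relation during generation. At clinical slice thickness ventricular
structures span tens of slices and contain no single-slice-thick segments;
on a 24-slice grid, voxelization of thin oblique channels would otherwise
create them, and the 2.5D pass would then erode *correct* anatomy — the
evaluation would measure a grid artifact rather than the method.

What the phantoms do **not** emulate: real anatomy (sulcal/subarachnoid CSF,
ventricle topology), partial-volume effects, beam hardening, shunt hardware,
scanner-dependent HU calibration, motion. Passing the synthetic experiments
therefore demonstrates that the implementation learns, segments, reconciles
slices and measures volumes correctly under controlled contrast and noise —
not clinical-grade performance, which requires real annotated CT.

## Scaled-down experiment

The end-to-end test trains the desk profile on 8 phantom exams (24×64×64,
~192 slices), evaluates on 2 held-out exams, and asserts mean held-out dice
≥ 0.85 with postprocessing and that postprocessing does not reduce the mean
dice. Problem sizes (grid, cohort, 4 epochs, batch 10) are the package's
desk-scale study conditions; a second seed covers run-to-run variation of
the stochastic pipeline. Typical results: dice ≈ 0.85–0.95 per exam,
with postprocessing adding a few 10⁻³.

## Known limitations

- 2D inference; no 3D convolutions or context beyond the 2.5D pass.
- The numpy core is CPU-only and sized for the desk profile; the full
  512×512 profile builds and runs but is not practical to train here.
- Empty-baseline volume change reports an undefined percentage rather than a
  number.
- Single-pass postprocessing removes genuinely isolated single-slice
  structures; at clinical slice thickness these are almost always errors,
  but very small ventricle compartments could in principle be affected.
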