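# Methods

## The classification problem

Gallbladder disease spans conditions with distinct sonographic
signatures: hyperechoic gallstones with distal acoustic shadows,
inflammatory wall thickening (cholecystitis and its membranous/gangrenous
forms), wall defects (perforation), benign wall lesions (polyps,
adenomyomatosis), malignant masses (carcinoma), nonspecific wall
thickening, and lumen-free abdominal/retroperitoneal fields.  `gallnet`
implements a nine-class convolutional classifier for 128x128 grayscale
ultrasound images built around multi-scale feature extraction, together
with the full training/evaluation pipeline and two from-scratch
explanation methods (Grad-CAM and LIME).

## Architecture

The network is a six-stage convolutional stack.  Each stage is either

* a plain stage: same-padded `k x k` convolution (default 3x3) -> batch
  normalization -> ReLU -> 2x2 max-pool, or
* a multi-scale feature-extraction (MSFE) stage: three parallel
  same-padded branches with 1x1, 3x3 and 5x5 kernels, each
  conv -> BN -> ReLU, concatenated along channels, followed by a
  post-merge batch normalization and the 2x2 max-pool.  The branches
  contain no pooling, so all three preserve spatial extent until the
  merge; the merged channel count is f1 + f3 + f5.

Six pooled stages reduce 128 -> 2, so the head flattens a
`2 x 2 x C_final` tensor into two hidden dense layers (256 and 128
units, ReLU, dropout 0.1 after each) and a 9-way softmax.  An L2 penalty
of `0.01 * sum(W^2)` is applied to all dense-layer weights (biases and
batch-norm parameters excluded).

Convolution is implemented as cross-correlation (no kernel flip), the
deep-learning convention; the package carries a literal valid-region
reference implementation (`conv2d_reference`) against which the layer
convolutions are tested on input interiors.

### Pinned configurations

The per-stage widths are free configuration.  Two defaults are pinned by
the published trainable-parameter budgets:

| config   | stages                                                         | parameters |
|----------|----------------------------------------------------------------|-----------|
| full     | conv16, MSFE(16,16,16), conv96, MSFE(32,32,32), conv256, conv448 | 1,907,705 (1.91 M) |
| ablation | conv16, conv32, conv48, conv96, conv160, conv256                 | 865,209 (0.87 M) |

The ablation ("without MSFE") model is a separately tuned narrower
six-conv network rather than the full model with its MSFE stages swapped
in place: the full model's deep-stage widths alone exceed the 0.87 M
budget, so an in-place swap cannot reach it.  MSFE stages sit at
positions 2 and 4; placing them among the six pooled stages (rather than
adding extra pooled blocks) is forced by geometry — eight pools would
shrink a 128-pixel image below one pixel.

### Numerical engine

No deep-learning framework is used: layers, backward passes and the Adam
optimizer are implemented in NumPy (`gallnet.nn`).  Convolution runs as
im2col + GEMM, as a plain GEMM for 1x1 kernels, or as one GEMM per
kernel offset (shift-and-accumulate) at large spatial extents where the
im2col patch matrix is memory-bound; the three strategies are
mathematically identical and the unit tests check each against a
brute-force nested-loop oracle to 1e-10.  Parameters default to float32
for speed; float64 is available and used in the gradient-check tests.

* Weight init: variance-scaling fan-in uniform (`U(+-sqrt(6/fan_in))`),
  seeded; two builds with the same seed are bit-identical.
* Batch normalization: per-channel over (N, H, W), eps 1e-5, trainable
  scale/shift.
* Softmax is computed shift-invariantly (max subtraction) so logits of
  magnitude ~100 cannot overflow.
* Pooling on an odd spatial extent raises rather than silently padding;
  the default geometry never produces odd extents.

## Training protocol

Adam (beta1 0.9, beta2 0.999, eps 1e-7) at base learning rate 1e-4 with
time-based decay `lr / (1 + 0.2 * epoch)` ("decay rate 0.2"; the
schedule is configurable to exponential or none), sparse categorical
cross-entropy (probability floor 1e-12) plus the L2 penalty, batch 32,
at most 10 epochs.  Early stopping monitors validation accuracy with
patience 3 (strict improvement, min-delta 0); the checkpoint keeps the
earliest epoch with minimal validation loss, and the returned model is
that checkpointed state.  Reported losses include the L2 term, i.e. they
are the optimized objective.  Training data are shuffled per epoch and
augmented on the fly; validation/test data never are.

### Inference-time batch-norm statistics

With 80 images/class the training epoch has only 18 optimizer steps.  An
exponential moving average of batch statistics (the usual inference
mechanism) trails the weights by roughly `1/(1 - momentum)` steps, which
at this scale leaves validation metrics evaluating a model that no
longer exists: in a diagnostic run, validation accuracy was 0.78 under
batch statistics but 0.58 under the EMA, and even *training-set*
accuracy dropped to 0.625 in inference mode.  The trainer therefore
re-estimates every BN layer's inference statistics before each
validation pass as an exact cumulative average of batch statistics over
a class-balanced strided subsample (at most 256 images) of the
unaugmented training stream under the current weights — the standard
"precise BN" / `update_bn` remedy.  The EMA (momentum 0.8) still runs
during training and is what a user gets without re-estimation.

### Reproducibility

`TrainConfig.seed` spawns three independent child streams (epoch
shuffles, augmentation draws, dropout masks); with fixed inputs a run is
bit-reproducible, including the history CSV.  Checkpoints (`.npz`) store
parameters, BN statistics and the architecture document, so restoring
one reproduces the recorded best validation loss to float precision.

## Data handling

Images load from a class-per-subdirectory tree, are converted to
grayscale by channel averaging (ultrasound is inherently single-channel;
stored RGB is redundant), resized to 128x128 bilinearly and scaled by
1/255.  The split is stratified per class with the rounding rule
`train = round_half_up(0.8 N)`, `test = round_half_up(0.1 N)`,
validation = remainder; this rule reproduces the published per-class
train/test/validation table of the gallbladder ultrasound corpus exactly
(1,069 test and 1,069 validation images over 10,692).  Membership is a
seeded permutation within each class after sorting by path, so the split
depends only on the record set and seed, not input order.  "Shuffled
10,000 times" is modeled as a single seeded uniform permutation — a
composition of uniform shuffles is itself a uniform shuffle.

Augmentation (training only, applied per epoch): shear coefficient
uniform in +-0.2, zoom factor uniform in [0.8, 1.2], horizontal flip
with probability 0.5; bilinear resampling with reflect padding about the
image center, output clipped to [0, 1].  The shear/zoom bounds are
configurable; 0.2 is a common default for this augmentation style.

The split is image-level, matching the published table; patient-level
splitting (which would rule out same-patient leakage) is noted as a
limitation below.

## Synthetic phantoms

The phantom generator exists so that every stage of the pipeline is
exercisable and testable without clinical data.  Each 128x128 phantom is
an anatomy layer times a speckle field:

* Speckle: a Gaussian white field, low-pass filtered (sigma 1.1 px) and
  squared — the first-order model of fully developed speckle with
  exponential-like intensity statistics — normalized to unit mean and
  blended toward 1 with modulation depth 0.25.
* Anatomy: mid-gray tissue (mean 0.45) with smooth heterogeneity, a dark
  elliptical anechoic lumen, an echogenic wall, and one class motif per
  condition (bright shadowing stones; fascia-banded lumen-free field;
  bright thick wall with pericholecystic rim; irregular wall with
  intraluminal membranes; angular wall gap with adjacent fluid;
  wall-attached non-shadowing polyps; thick wall with anechoic
  intramural pockets and comet-tail streaks; heterogeneous
  irregular-margin mass; extreme striated wall).

Geometry (lumen axes, wall thickness, focus counts/radii) is drawn per
image from per-class ranges, so phantoms vary within a class while the
class signature is consistent; `(class, seed)` fully determines the
pixels.  The generator's job is *class-separable* synthetic data: the
signatures are deliberately strong enough that the full model reaches
high validation accuracy within the 10-epoch protocol, and a raw-pixel
nearest-centroid baseline already exceeds four times chance.  What
passing tests on phantoms demonstrate is that the architecture,
optimizer, data pipeline and explainers function correctly end-to-end —
not that the model would reach any particular accuracy on clinical
ultrasound, where class boundaries are far subtler, device- and
operator-dependent, and confounded by patient overlap.

A `confusability` option (off by default) adds stone-like distractor
foci to the classes clinically confusable with gallstones, for
qualitative studies of the error structure.

## Explainers

Grad-CAM: channel weights are the spatial mean of the gradient of the
target class *logit* (pre-softmax — standard and better conditioned than
the probability) with respect to a convolutional stage's activations;
the rectified weighted sum is upsampled bilinearly and min-max
normalized (an all-zero map stays all-zero).  The default target is the
deepest stage's pre-pool activation map.  Because the engine's backward
passes cover inference mode, the gradient is taken with BN in inference
statistics and dropout off.

LIME: superpixels come from grid-initialized Lloyd iterations on
(y, x, intensity) features — spatial coordinates scaled by the expected
superpixel spacing, intensity (lightly smoothed, sigma 1.5 px) weighted
by a compactness factor of 3 — followed by a connectivity cleanup that
merges stray fragments into the neighbor with the longest shared
boundary.  1000 binary keep/drop masks (keep probability 0.5, the
all-ones mask always included) perturb the image, dropped regions
replaced by the image mean (black is a meaningful, anechoic ultrasound
signal, so it is not a neutral baseline); responses are the model's
class probability.  A ridge regression (penalty 1e-3, intercept
unpenalized) weighted by `exp(-d^2 / 0.25^2)` with d the dropped
fraction yields per-region coefficients; the top-5 regions by |coef|
split into a positive (green) and negative (red) mask.  As the ridge
penalty tends to zero the fit equals exact weighted least squares, which
the tests verify against a closed-form solution.

## Known limitations

* Phantoms idealize ultrasound: no depth-dependent attenuation or focal
  zones, no probe-geometry fan, no patient-level correlation structure.
* The split is image-level; with several images per patient in the real
  corpus this overestimates generalization.
* Single CPU float32 training: throughput, not fidelity, bounds the
  problem sizes used in the test suite (80 phantoms per class for the
  end-to-end run, 12 per class for the bit-reproducibility run).
* The superpixel count is approximate (target +-30%), as for any
  clustering-based segmentation.
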