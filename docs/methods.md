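# Methods

This note documents the models and procedures implemented in `affetds`, the
design decisions behind them, the synthetic data the package is validated on,
and the limits of what those validations show.

## Problem setting

The package detects *tumor deepfakes* in grayscale 2-D MRI-like images: local
edits that either insert an artificial lesion into a genuine scan or erase a
real lesion and inpaint the gap. The detector is a two-member ensemble —

* an RBF-kernel SVM over a fused handcrafted + deep feature vector, and
* a lightweight convolutional network over the raw (preprocessed) pixels —

combined by soft voting with weights proportional to each member's
validation AUC, and hardened by adversarial training with FGSM and PGD.

## Synthetic corpus

Clinical forged-MRI corpora are built from restricted archives plus
unpublished editing pipelines, so the package ships a generator that
reproduces the *statistical task* rather than the images themselves.

**Phantoms** (genuine class). Each image is an elliptical head (randomly
jittered center, semi-axes 88x72 px at the 224-px scale +-5%, rotation
+-0.15 rad) with a bright skull-rim band (intensity 0.80), tissue interior
(0.55), a dark ventricle pair (0.35), dark background (0.05), and
band-limited tissue texture: white noise low-passed with a sigma = 6 px
Gaussian, scaled to amplitude 0.06. With texture amplitude 0 the image is
exactly piecewise constant — a property the tests exploit.

**Insertions.** A lesion outline is an ellipse warped by random 2nd-5th
order angular harmonics (irregularity drawn from [0.2, 0.6]). Default radii
are drawn from 10-22 px and the intensity offset from +-[0.20, 0.35]
relative to surrounding tissue (25% of lesions hypointense), with interior
texture of amplitude 0.03. The lesion is blended through a 2-px Gaussian
feather (kernel truncated at 4 px), so every pixel farther than 4 px from
the binary mask is bit-identical to the source phantom. These ranges were
fixed at design time to emulate *clinically apparent* lesions: a lesion
whose contrast is inside the tissue-texture band is not merely hard but
informationally absent after denoising, and a corpus dominated by such
lesions cannot validate the pipeline.

**Removals.** A region (the footprint of a previously inserted lesion) is
refilled with (a) the mean intensity of a 5-px boundary ring, (b) additive
band-limited texture rescaled to the ring's standard deviation, and (c) an
affine renormalization forcing the region's mean/std onto the ring's. This
is the classical region-fill / texture-synthesis / intensity-normalization
inpainting signature: first and second moments match the surroundings, but
the spatial autocorrelation does not.

**Corpus composition.** 774 genuine + 604 manipulated images (manipulated
half insertion, half removal, remainder to insertion), stratified-split
70/15/15 with round-half-up on the validation and test counts per class —
at full scale this yields 964/207/207. All randomness descends from one
root seed; corpora are reproducible byte-for-byte, images are stored as
8-bit lossless PNG.

What the generator does *not* emulate: scanner noise distributions
(Rician), bias fields, anatomy beyond a two-ventricle ellipse, 3-D
structure, and GAN-specific inpainting artifacts. Passing tests on this
corpus show the pipeline's machinery is correct and that it detects
moment-matched local edits; they do not certify performance on clinical
data.

## Preprocessing

Pinned order: bilinear resize to 224x224 -> per-image min-max normalization
to [0, 1] (a constant image maps to all zeros) -> Gaussian denoising with
sigma = 1.5 px, reflective boundaries -> clip to [0, 1]. Per-image (rather
than per-dataset) normalization is the simplest contract and is applied
identically at train and test time.

## Feature fusion

* **HOG branch (3780-d).** The image is resized to the canonical 64x128
  Dalal-Triggs window; 8x8-px cells, 2x2-cell blocks at 1-cell stride, 9
  unsigned orientation bins, L2-Hys (clip 0.2) normalization:
  7x15 blocks x 4 cells x 9 bins = 3780. This is the unique standard
  geometry producing that dimension.
* **Deep branch (2048-d).** A ResNet-style convolutional backbone (7x7/2
  stem, 3x3 max-pool/2, four residual stages of widths 32/64/128/256, a 1x1
  expansion to 2048, global average pooling) with He-initialized weights
  drawn from a fixed seed. Random convolutional features are a
  deterministic, download-free embedding; the backbone is deliberately
  shallower than a full 50-layer network so feature extraction stays cheap
  on one CPU, and its output length is exactly 2048 for any valid input.
  Grayscale input is replicated to three channels and standardized with the
  usual natural-image per-channel constants.
* **Fusion.** Concatenation, deep features first (positions 1-2048,
  1-based), HOG second (2049-5828); no rescaling at fusion time.

## Classifiers

**SVM.** Features are z-scored with training-split statistics only
(zero-variance dimensions get unit scale). C and gamma are grid-searched
(C in {0.1, 1, 10, 100}; gamma in {1e-4, 1e-3, 1e-2, 1e-1, 1/d}) by
validation AUC of the decision function, ties resolved toward smaller C
then smaller gamma. Probabilities come from a Platt sigmoid (logistic
regression on validation decision values); if the fitted sigmoid is
non-monotone (validation AUC below chance) the model falls back to a plain
logistic link.

**CNN.** Three conv blocks (3x3 same-padding conv -> ReLU -> 2x2 max-pool;
widths 16/32/64), a 2x average-pool (`train.head_downsample`), then flatten
into FC-128 -> ReLU -> FC-2 -> softmax. Inputs are standardized inside the
network by the fixed map (x - 0.5) * 2: without centering, optimization
from He-initialized weights plateaued at the class prior on every
configuration tried, while the centered network trains reliably — the
scaling factor re-enters the input-gradient chain rule used by the
attacks. Optimization is Adam (lr 1e-3, batch 16, decoupled weight decay
1e-4 on weight matrices), early stopping on validation loss with patience
5 under an epoch cap of 50; the returned weights are those of the
best-validation-loss epoch. Batch 16 (rather than the more conventional
32) doubles the updates per epoch, which matters at a few hundred training
images; the extra head pool quarters the FC parameter count and measurably
improved generalization (test AUC 0.94 vs 0.85 without it on the synthetic
task). The network is implemented in NumPy with explicit backpropagation
(im2col convolutions evaluated as BLAS products); all gradients —
including the input-pixel gradient the attacks require — are verified
against an independent float64 reference implementation in the test suite.
A configurable global max/avg pooling head exists (`train.head_pool`), but
flatten is the default: at these sample sizes the pooled heads failed to
fit even the training set.

After training, the CNN's "manipulated" probability is Platt-recalibrated
on validation logits (monotone fits only; ranking and hence AUC are
unchanged). The raw softmax of a small network trained on few images is
routinely shifted relative to the 0.5 decision threshold — one observed
run had test AUC 0.89 but only 0.69 accuracy at the fixed threshold —
and the ensemble's fixed-threshold soft vote needs both members'
probabilities on a common calibrated scale, exactly why the SVM is
calibrated the same way.

A trailing partial minibatch is dropped when at least one full batch
exists, which keeps per-epoch update counts and internal buffer shapes
constant; with 32-image batches this discards at most 31 samples per epoch
from the shuffled order, a different subset each epoch.

## Adversarial training

FGSM takes one signed-gradient step of size epsilon and clips to [0, 1].
PGD starts from a seeded uniform point in the infinity-norm epsilon-ball
and iterates k steps of size alpha with projection onto the ball and the
valid range after each step, recomputing the gradient at the current
iterate. Defaults: epsilon = 0.03 (~8/255, the conventional budget),
alpha = 0.007, k = 10 — all configurable, since no standard values are
forced by the problem. `sign(0) = 0`.

The training schedule is: (1) train the CNN on clean images to the early
stop; (2) craft FGSM and PGD copies of a per-class random subset of the
training split (`attack.fraction`, default 0.5) against that converged
model — attacks against a barely-trained network are little more than
noise; (3) fine-tune on the augmented set for at most
`train.finetune_epochs` (default 10) epochs, with the incoming clean
weights as the early-stopping baseline so adversarial fine-tuning can
never end worse on validation than it started. Perturbed copies keep their
original labels and provenance flags, and the augmented image set then
flows through feature extraction into SVM training as well. Attack
crafting batches 16 images per gradient call; because the per-pixel sign
of the batch-mean gradient equals the per-image sign, results match
per-image crafting (PGD random starts are seeded per batch).

## Ensemble

Weights w_i = AUC_i / (AUC_SVM + AUC_CNN) from validation AUCs;
p_final = w_SVM * p_SVM + w_CNN * p_CNN; decision threshold 0.5 with ties
flagged "manipulated" (in a screening setting the ambiguous case is the
one to surface). p_final is a convex combination, hence monotone in each
member and bounded by them — both properties are tested.

## Evaluation

"Manipulated" is the positive class. Confusion counts, accuracy, precision,
recall, F1 (undefined ratios reported as `None`, never 0); ROC-AUC
(trapezoidal, ties one half); average precision (step interpolation);
reliability tables over 10 equal-width bins (bin = min(floor(10 s), 9),
empty bins omitted); median/IQR probability summaries (linear-interpolation
percentiles). The AUC implementation is cross-checked against brute-force
positive/negative pair counting in the tests.

**Wilcoxon signed-rank.** Zero differences dropped; midranks for tied
magnitudes; statistic W = min(W+, W-). The two-sided p-value is exact —
P(W+ <= W) + P(W+ >= T - W) over all 2^n sign assignments — for n <= 12,
and a normal approximation with tie correction beyond. This variant is
implemented in-package because the pinned conventions (exact-with-midranks,
zero-drop, p = 1 when all differences vanish) are not exposed as one mode
by standard libraries; the implementation is cross-checked against an
exhaustive enumeration oracle and against `scipy.stats.wilcoxon` on
tie-free inputs. Ensemble-vs-baseline comparisons are reported with raw and
Holm-adjusted p-values across the two baselines per metric.

## Problem sizes used in automated runs

The shipped test suite and the acceptance script run the full pipeline at
reduced scale chosen to keep single-CPU runtimes reasonable: a 300-image
corpus (210/45/45 split, epoch cap 50 with patience 6, fine-tune cap 8,
augmentation fraction 0.5, root seed 1) for the single-seed end-to-end
run, and five 140-image corpora (epoch cap 14, patience 5, fine-tune cap
4, fraction 0.25) for the five-seed ensemble-vs-member comparison. At
these scales the held-out test splits contain 45 and 21 images, so
accuracies carry sampling noise of several percentage points per seed;
the five-seed comparison is about means. Full-scale (1378-image) runs use
the same code path via `affetds train`.

Corpus-to-corpus difficulty varies genuinely at these scales: a seed whose
lesion draws happen to be faint drags both members down together, which
bounds what any member-level improvement can recover. The acceptance
script reports the single-seed end-to-end metrics it computes; the test
suite computes the five-seed comparison.

## Known limitations

* Backbone weights are random; with torchvision-style pretrained weights
  the deep branch would likely contribute more discriminative power. The
  pipeline accepts any embedding with the documented contract.
* The SVM sees adversarial images only through the feature map; no attack
  is crafted against the SVM itself (it exposes no pixel gradient).
* Calibration of the ensemble is inherited from its members; no post-hoc
  ensemble-level recalibration is performed.
* The synthetic task's difficulty is controlled by generator parameters;
  conclusions about robustness transfer to clinical data only
  qualitatively.
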