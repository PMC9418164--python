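# Methods

## Problem setting

Given a small labeled set X = {(x_i, y_i)} of RGB endoscopy-style images with
binary polyp masks and a larger unlabeled set Z = {z_i}, the goal is a
segmentation network that exploits Z. Three mechanisms are combined:

1. **Mean teacher.** Two copies of the network are kept: a *student* with
   weights θ trained by gradient descent, and a *teacher* whose weights θ′
   are an exponential moving average,

       θ′_t = α θ′_{t−1} + (1 − α) θ_t ,

   updated once per optimizer step. α = 0 reduces to the π-model (teacher =
   current student); α = 1 freezes the teacher. The teacher produces the
   consistency targets and the pseudo-labels, and is the network used for
   validation, testing and prediction.

2. **Perturbation-consistency loss (CL).** For an unlabeled batch the teacher
   predicts the clean images, giving a reference map z_y. The student
   predicts perturbed versions of the same images; each prediction is mapped
   back to the reference frame (transformation consistency) and penalised by

       CL = mean_k ‖ align_k(student(T_k(z))) − z_y ‖²  (pixel mean),

   with up to three perturbations T_k per step: random scaling, additive
   Gaussian noise, right-angle rotation. The total loss is
   `L + λ·CL` where L is the supervised binary cross-entropy on the labeled
   sub-batch and λ follows a sigmoid ramp (exp(−5(1−e/E_ramp)²)) from 0 to
   λ_max.

   The reference branch is deliberately the *teacher* and the perturbed
   branches the *student*: a consistency term computed from teacher outputs
   alone would have zero gradient with respect to the trained weights and
   could not influence learning. This is the standard transformation-
   consistent mean-teacher arrangement.

3. **Continuous update of pseudo-labels (CUPL).** Every `interval` epochs
   after a warm-up, the teacher soft-labels every unlabeled image. Images are
   ranked by the pixel-mean squared disagreement between teacher and student
   maps; only the fraction `keep_fraction` with the lowest disagreement is
   accepted (quantile rule — the original description says "low MSE" without
   a threshold, and a quantile is scale-free across training stages). Each
   accepted map is averaged element-wise with the image's previous-round
   pseudo-label, damping oscillations; the result joins training through the
   combined loss

       Combined = (1/|X|) Σ BCE(labeled) + (1/|Z|) Σ BCE(pseudo) ,

   implemented per batch as the sum of the two sub-batch means. The
   round-averaging memory and the confidence filter operate on **soft** maps
   (that is where the confidence information lives), but the emitted training
   target is the 0.5-binarised map: the pseudo ground truth u_i is a binary
   mask, and training on soft teacher maps is self-distillation of a weaker
   signal, which measurably degrades the student
   (`CuplConfig.binarize_targets` switches this).

### Loss details

* BCE is the standard −mean[y log y′ + (1−y) log(1−y′)] with predictions
  clamped to [1e−7, 1−1e−7]; soft targets are accepted for pseudo-labels.
  (A published variant of the formula with a sign error degenerates at y=0;
  the standard form is used.)
* All losses are pixel means, so values are resolution-independent; the
  consistency loss additionally averages over the configured perturbations,
  which only rescales it by a constant.

## Network

A UNet++-style nested grid of nodes X[i][j] (level i halves resolution i
times; node channel width doubles per level from `base_channels`). Each
decoder node concatenates every previous node of its level with a
transposed-convolution (kernel 2, stride 2) upsampling of the node one level
below, applies a conv block, then a channel-then-spatial (CBAM-style)
attention gate. Every full-resolution decoder node feeds a deep-supervision
head (1×1 conv + sigmoid); the network output is the arithmetic mean of the
heads, and the supervised/pseudo BCE is averaged over heads.

The reference design uses a pretrained EfficientNet encoder. Here the encoder
column is a stack of plain conv+ReLU blocks (the `tiny` backbone, one 3×3
conv per node by default, `convs_per_block` configurable, no normalization
layers) with the identical nested decoder: the semi-supervised mechanics
under test do not depend on the encoder's pedigree, and the tiny backbone
trains in minutes on one CPU. The whole network, its reverse-mode autodiff
and the Adam optimizer are implemented on numpy (im2col + BLAS convolutions);
gradients are verified against finite differences in the test suite.

## Perturbations and alignment

* **Rotation** is restricted to {90°, 180°, 270°}: right-angle rotations are
  exact pixel permutations, so apply∘align is bit-exact and the consistency
  target is interpolation-free. Arbitrary angles would make the target depend
  on the resampling kernel.
* **Scaling** resizes the full frame by a factor in [0.8, 1.25], rounded to a
  stride-compatible size (the network is fully convolutional); alignment is
  the inverse bilinear resize. Exact invertibility is impossible for scaling
  on a fixed raster; round-trips are accurate to interpolation error
  (≲0.02 max abs on band-limited content), which the tests assert. A
  center-crop/pad variant was rejected because it leaves border regions of
  the consistency target undefined.
* **Gaussian noise** (default sd 0.03 on the [0,1] intensity scale — visible
  but not destructive) is seeded per draw and needs no alignment.

## Synthetic fixtures

The generator emulates the statistics that matter for the method: one or two
bright, pink-shifted blobs (ellipses with low-frequency harmonic boundary
modulation, mimicking variable polyp shape/scale) on a low-frequency textured
background with i.i.d. pixel noise and per-image illumination variability,
plus the exact mask. Defaults: 64×64, contrast 0.45 with a per-image ×0.5–1.0
jitter, per-image tone shift ±0.16, background texture span ±0.06, noise sd
0.10, deform amplitude 0.25, blob radius 0.12–0.30 of the side; an optional
radial vignette (`vignette_strength`, default off) adds further difficulty.
The illumination terms were calibrated so that 20 labeled images leave
visible headroom (a baseline trained on all 220 training masks scores
several Dice points higher than one trained on 20) without pushing
convergence past the study's epoch budget. At full contrast and zero noise a
luminance threshold recovers the mask exactly (tested), and per-image Otsu
thresholding exceeds Dice 0.8 on noise-free images, so the foreground is
learnable by construction.

What the fixtures do **not** emulate: specular highlights, instrument
shadows, vignetting, colour calibration drift, multiple tissue classes, or
the long-tailed size distribution of real polyps. Passing the fixture study
therefore shows that the training mechanics behave as designed (CL and CUPL
add signal from unlabeled data), not that clinical-grade accuracy would be
reached on Kvasir-SEG-like data.

## Desk-scale study protocol

The regime comparison (baseline vs +CL vs +CL+CUPL) runs at:
64×64 images, `tiny` backbone with 3 levels / 8 base channels, 375 fixtures
split 80:10:10 (37 validation / 38 test images keep the evaluation noise
below the effect sizes), 20 labeled / 200 unlabeled, 60 epochs, batch 4
(2 labeled + 2 unlabeled — 600 optimizer steps, enough to converge inside
the epoch budget), Adam lr 2e−3, λ_max 1 ramped over 15 epochs, CUPL
warm-up 40 epochs / interval 10 / keep fraction 0.8, teacher α 0.99,
three seeds.

Choices that differ from the full-scale defaults, and why:

* **lr 2e−3** (not 1e−5): the published rate protects a *pretrained* encoder;
  the tiny backbone trains from scratch and, at this step count, needs the
  larger rate to converge within the budget.
* **α 0.99** (not 0.999): the EMA horizon 1/(1−α) is kept at roughly a third
  of the run's ~300 optimizer steps, matching the proportion the published
  setting implies at thousands of steps; with α 0.999 the teacher would
  still reflect its initialisation when training ends.
* **CUPL warm-up 40 of 60 epochs**: pseudo-labels are generated only once the
  semi-supervised model has essentially converged, mirroring the stated
  procedure of training to convergence before the first generation. Earlier
  generation trains the student on near-random teacher maps and degrades it.
* **Labeled sub-batch fixed at batch/2 in every regime**: all regimes see the
  same number of Adam steps and the same supervised stream; the baseline
  simply leaves the unlabeled half of each batch unused. Without this the
  baseline receives ~40% fewer optimizer steps per epoch and the comparison
  confounds regime with step count.
* `RunConfig` defaults keep the full-scale published protocol (200 epochs,
  batch 40, lr 1e−5, α 0.999, pseudo-label refresh every 10 epochs, 256×256
  inputs) for use on real datasets.

## Numerical and degenerate-input conventions

* Evaluation: per-image confusion counts at threshold 0.5, macro-averaged.
  If a score's denominator is empty, the image scores 1 when the prediction
  is also empty, else 0. Dice = 2J/(1+J) holds per image by construction.
* Confidence filter ties break lexicographically by image id; the filter is
  monotone in `keep_fraction`.
* Masks binarise at 0.5 after decoding to [0,1]; images load as [0,1]
  float32; image resize is bilinear, mask resize nearest-neighbour.
* Splits, weight init, batch order, perturbation draws and noise fields all
  derive from one integer seed via independent child streams, so runs are
  bit-reproducible on a platform, and a `cl` run with zero unlabeled images
  and λ=0 is bit-identical to `baseline`.

## What the desk-scale study can and cannot resolve

The comparison resolves the consistency-loss effect: it is small but
consistent (the acceptance suite checks the regime ordering, and the CL gain
has shown the same sign across seeds). The CUPL effect is at or below the
study's resolution: with 60 epochs, only two pseudo-label refresh rounds fit
after convergence, whereas the mechanism is designed as a long *continuous*
refresh phase (a 10× longer schedule at full scale, with far more unlabeled
images and a pretrained encoder). At this scale the teacher's pseudo-labels
sit at the student's own generalization level, so their BCE term behaves as
self-distillation and can trade recall for precision instead of adding
information. The accepted-vs-rejected pseudo-label audit (confidence-filter
validity) is scale-robust and is asserted separately.

## Known limitations

* No pretrained encoder: absolute accuracy on real endoscopy data would need
  the full-scale configuration and transfer learning; this package's claims
  are about the semi-supervised mechanics.
* CPU-bound numpy training: practical up to roughly 128×128 inputs and
  ~10⁵ parameters; the architecture itself scales, the training speed does
  not.
* The labeled/unlabeled sets are assumed to share a distribution (the
  fixtures enforce this); distribution shift between them is known to produce
  false-positive pseudo-labels and is out of scope.
* Batch-level normalisation of the combined loss approximates the set-level
  1/|X|, 1/|Z| weights under uniform sampling.
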