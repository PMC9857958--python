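# Methods

This note documents the models, procedures and numerical choices behind
`sffnet`, in the spirit of a model-description appendix: what is computed,
under which assumptions, and what the synthetic experiments do and do not
demonstrate.

## Problem setting

Mass-forming intrahepatic cholangiocarcinoma (MF-ICC) and hepatocellular
carcinoma (HCC) require different treatment but can look alike on
T2-weighted MRI. Radiologically, the most reliable discriminative cue is
the lesion *margin*: HCC tends to show a sharp boundary with an enhancing
pseudocapsule rim, while MF-ICC margins are blurred and irregular. The
package implements a slice-level binary classifier built around that cue:
a mask-guided preprocessing step that preserves the lesion edge and its
immediate surroundings, and a residual CNN that fuses shallow
(edge/texture) with deep (semantic) feature maps.

## Semi-SP preprocessing

Given a slice and a radiologist-style binary lesion mask:

1. **Bounding box.** Tight axis-aligned box over the mask foreground
   (row-major, 0-based, inclusive bounds).
2. **Square ROI.** Side = `ceil(scale × max(box height, box width))` —
   i.e. the maximal lesion diameter along an image axis — centered on the
   integer midpoint of the box. `scale` is 1 for Semi-SP, 2 and 3 for the
   enlarged comparison strategies. The side is clamped below at 8 px so a
   near-point mask cannot produce a degenerate crop. The diameter is the
   bbox extent, not the Feret diameter: it is deterministic, cheap, and
   sufficient for a containing square once combined with bbox centering.
3. **Crop + resize.** The square is cropped with zero fill where it
   leaves the image (only border lesions) and resized to the target patch
   size (default 224×224) by separable bilinear interpolation with
   half-pixel centers. No anti-aliasing filter is applied; the same
   interpolation kernel is used everywhere in the package, and it is
   tested pixel-for-pixel against a direct per-pixel oracle.
4. **CLAHE.** Contrast-limited adaptive histogram equalization sharpens
   edge texture. Defaults: clip limit 2.0 (in multiples of the uniform
   per-tile histogram level), 8×8 tile grid, 256 bins. Internally this is
   `skimage.exposure.equalize_adapthist` with `clip_limit = ours / nbins`,
   which preserves the clip-level convention exactly; tiling details
   (reflect padding, high-resolution internal histogram) follow skimage.
   A zero-contrast patch is returned unchanged.

Five strategies share this machinery: `semi_sp` (scale 1), `double`,
`triple`, `whole_image` (full slice resized, no CLAHE — the
"no segmentation" control), and `lesion_only` (background zeroed by the
mask before cropping). CLAHE is applied in every mask-guided strategy so
the comparison isolates ROI geometry, not enhancement.

## Geometric augmentation

Training/validation patches are expanded by random affines — rotation
(±15°), isotropic scale ([0.9, 1.1]), translation (≤10% of the side) —
composed in fixed order rotate→scale→translate about the patch center and
resampled once (bilinear, zero fill). Each copy is a pure function of
`(seed, patch identity, draw index)`, so datasets rebuild bit-identically.
Patches flagged as test split are refused outright: the held-out set is
never augmented. The ranges are configurable; the defaults are mild
enough to preserve the margin phenotype.

## SFFNet

A ResNet101-style bottleneck backbone with three modifications:

* **CBAM in the stem** (after conv7×7/s2 → BatchNorm → ReLU, before the
  3×3/s2 max-pool): channel attention (shared two-layer bottleneck,
  reduction 16, applied to average- and max-pooled descriptors, summed,
  sigmoid), then spatial attention (7×7 convolution over the channelwise
  mean and max maps, sigmoid). Attention is kept out of the residual
  blocks so backbone checkpoints remain loadable.
* **SRB residual blocks**: pre-activation bottlenecks
  (BN→ReLU→1×1→BN→ReLU→3×3(stride)→BN→ReLU→1×1) with *no* batch norm
  after the final 1×1 — consecutive stages otherwise stack redundant
  normalizations. The projection shortcut (strided 1×1 + BN) is standard;
  with a zeroed branch the identity-shaped block is exactly the identity,
  which the tests assert to zero error. No activation follows the
  addition (pre-activation convention).
* **MFF multilayer feature fusion**: with X0 the stem+CBAM output (S/2
  grid), X3 the first-stage output (S/4) and X6 the last-stage output
  (S/32),

      FL  = concat(X0, up2(X3))
      Ffu = concat(FL, up16(X6))

  using bilinear upsampling; channel counts add (64+256+2048 = 2368 for
  the default widths). The tap points are the unique standard-backbone
  resolutions for which ×2 and ×16 upsampling both land on X0's grid.
  The classifier head is global average pooling over Ffu followed by one
  fully connected layer to 2 logits — the minimal head. Because the
  spatial mean of a concatenation is the concatenation of spatial means,
  the head pools X0, up2(X3) and up16(X6) separately; the mean of a
  bilinearly upsampled map is a fixed linear functional of the source
  map, so Ffu itself is only materialized when feature maps are
  requested. This is an exact identity, not an approximation, and is
  asserted numerically.

Depth presets: `full` = (3, 4, 23, 3) blocks (101-layer), `reduced` =
(1, 1, 1, 1) with identical widths and resolutions, sized for CPU-scale
experiments. Input size may be any multiple of 32 (default 224); inputs
are single-channel. Initialization is He-normal (fan-out) for
convolutions, unit/zero for norms, with an explicit seed. Checkpoints are
NumPy `.npz` name→array archives; loading matches by name and shape and
adapts a 3-channel stem to grayscale by channel averaging.

The layers themselves run on a small NumPy reverse-mode autodiff library
(`sffnet.nn`): convolutions are lowered to BLAS matrix products via
im2col, bilinear upsampling is a pair of dense interpolation-matrix
products (so its adjoint is exact), and batch norm uses the standard
closed-form backward. All backward passes are verified against central
finite differences.

## Data splitting and training protocol

Lesions (not slices) are split 6:2:2 into train/validation/test,
stratified by class, by a seeded shuffle with largest-remainder rounding;
every slice inherits its lesion's split, so no tumor leaks across splits.
The default optimization protocol is momentum SGD (momentum 0.9, weight
decay 0) on 2-class cross-entropy, initial learning rate 0.001 decayed
×0.1 every 30 epochs, batch 16, 100 epochs; the momentum value is a
declared conventional default. The checkpoint kept is the one with the
highest validation accuracy, earliest epoch on ties.

Metrics are computed per slice: per-class precision/recall/F1 from the
confusion matrix (rows = truth, columns = prediction; order HCC, MF-ICC),
overall accuracy, and ROC-AUC by explicit threshold sweep with
trapezoidal integration (equal to the Mann–Whitney concordance
statistic, which the tests check exhaustively for n ≤ 50). Per-class AUC
treats each class as positive in turn; the headline positive class is
MF-ICC. Zero denominators yield 0 with a recorded warning; a single-class
test set yields NaN AUC with a warning. A lesion-level majority-vote
report is available as a clearly separated extra. A seeded t-SNE
embedding (`embed_2d`) is provided for qualitative inspection only.

## Synthetic phantom cohort

Because the clinical cohort is private, the package ships a generator of
lesion phantoms that reproduces the discriminative structure, not MRI
physics. Lesions are star-convex blobs (base radius 12–40 px modulated by
3–4 random cosine harmonics) embedded in a smooth random-texture
background (level 0.35, correlation length 16 px, amplitude 0.08) with
additive Gaussian noise (σ = 0.03), in 256² slices:

* HCC-like: boundary blur σ = 0.8 px, bright rim annulus (+0.25, ±2 px),
  mild irregularity (0.10);
* MF-ICC-like: boundary blur σ = 3.0 px, no rim, stronger irregularity
  (0.25).

Both classes share the interior contrast (+0.22), so intensity alone is
not the signal. A lesion spans 3–6 slices sharing geometry with a
sphere-like radius profile and ±3% jitter, giving the intra-lesion
correlation that makes lesion-grouped splitting meaningful. The mask is
the unblurred blob support. Everything is deterministic in
`(seed, class, lesion index, slice index)`.

A deliberately trivial feature — mean gradient magnitude on the boundary
ring — separates the classes (AUC 1.0 at the default spec, within the
intended 0.75–1.0 learnability band): the task is learnable from edge
structure but only through the image, as the classifier sees no masks at
training time. What passing the synthetic benchmark shows is that the
preprocessing preserves the margin signal and the training loop can
extract it; it says nothing about clinical performance — real T2WI has
anatomy, bias fields, partial-volume effects and inter-patient
variability the phantoms do not model.

## The reference synthetic benchmark

`sffnet.pipeline.benchmark_run_config` pins the package's end-to-end
check: 30 lesions per class × 4 slices, Semi-SP preprocessing, the
reduced preset at 64×64 input, momentum SGD with lr 0.01 decayed ×0.1
every 10 epochs, batch 16, 25 epochs, evaluated on the held-out lesions;
run at three seeds and summarized by the median. The 64×64 resolution
and single-block depth are the package's CPU-scale problem size (the
fusion architecture is resolution-generic), and the shorter, warmer
schedule is the appropriate from-scratch recipe at this scale — the
0.001/30-epoch default assumes a pre-trained backbone. Typical result:
held-out slice accuracy ≈ 0.96, macro AUC ≈ 1.0.

## Numerical conventions and degenerate inputs

* Intensities live in [0, 1]; loading min–max normalizes, with
  zero-range images mapped to all zeros.
* Masks are strict {0, 1}; an empty mask is an error wherever a lesion is
  declared present.
* Bilinear interpolation uses half-pixel centers with edge clamping,
  everywhere.
* ROI squares may overhang the image; the overhang is zero-filled
  (border lesions would otherwise be partial functions).
* Ties: checkpoint selection → earlier epoch; majority vote → first
  class in order; ROC thresholds move tied scores as one block.
* All randomness flows through `numpy.random.Generator` seeded from
  explicit integers; no global RNG state is consumed.

## Known limitations

* No 3-D context: slices are classified independently; the lesion-level
  report is a post-hoc vote.
* CLAHE follows skimage's tiling internals, not OpenCV's 8-bit tiles;
  results differ in the low-order bits from OpenCV-based pipelines.
* Full-depth (101-layer) training at 224×224 is impractical on CPU; the
  full preset is exercised for forward-pass contracts only.
* The phantom generator does not model MRI physics (bias field, k-space
  artifacts) or anatomy; benchmark numbers are not clinical estimates.
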