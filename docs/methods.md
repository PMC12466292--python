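# Methods

This note documents the models, numerical conventions, and design choices in
`sonosiam`, in the spirit of a model-documentation page: what is computed, the
assumptions behind it, and what the synthetic experiments can and cannot show.

## Siamese architecture

The encoder is a shared-weight CNN: three conv blocks — 64 filters 5×5, 128
filters 5×5, 256 filters 3×3, each followed by ReLU, 2×2 max-pool (stride 2)
and dropout at rates 0.2/0.3/0.4 — applied to a 224×224 single-channel input,
yielding a 256×28×28 feature map (224 → 112 → 56 → 28 with 'same'-padded
convolutions). The flattened map (200 704 values) passes through dense layers
512 → 256 → 128; the 128-vector is the embedding. Two affine heads read the
embedding: abnormality (2 logits) and body part (3 logits). The
200 704×512 matrix alone holds ~102.8M of the 103.4M trainable parameters,
which is why the FP32 footprint is 413.7 MB (4 bytes/parameter, decimal MB).
The dense stack is described in the architecture only from 512 downward; the
flatten→512 layer is the only reading that reproduces that footprint, so it
is part of the reference spec here.

Weight sharing is structural: both pair members pass through the same layer
objects, and the training step sums the two branches' parameter gradients.
Initialisation is He-uniform (conventional for ReLU stacks); all biases start
at zero. `BackboneSpec.small(side)` is the CPU-scale variant (conv 8@5×5,
16@3×3; dense 64 → 32) used by the end-to-end experiments; every analytic
size/shape computation works for arbitrary specs.

## Losses

Pair labels follow the contrastive-loss formulation itself: y = 1 marks a
similar pair (the d² term pulls), y = 0 a dissimilar one (the squared hinge
max(m − d, 0)² pushes past margin m = 1). Some prose descriptions of this
loss family invert the label names; the formula is authoritative here. The
multi-task objective is

    L = w_c · L_contrastive + w_a · L_CE(abnormality) + w_b · L_CE(body part)

with defaults (1.0, 2.0, 0.5) — abnormality weighted up for clinical
priority, body part down as a regularizer — and a normalized preset
(0.6, 0.3, 0.1) available as `LossWeights.lambda_variant()`. Head
cross-entropies are computed on both images of every pair and averaged, the
only convention that lets the objective act per pair batch. Cross-entropy is
plain softmax CE; optional per-class weights exist but are off by default.
`distillation_loss` (0.5·CE + 0.3·KL + 0.2·MSE) is provided as a generic
teacher–student utility on caller-supplied scalars; no teacher network ships
with the package.

## Curriculum pair sampling

Stages are scheduled by training thirds (boundaries 1/3, 2/3 of epochs,
configurable): EASY draws both members within one source tag (dissimilar
pairs fall back to plain cross-condition contrasts when no single source
holds both conditions — the "obviously distinct" branch); MEDIUM draws
similar pairs across source tags (falling back to unrestricted same-condition
pairs on fully confounded manifests) and leaves dissimilar pairs
unconstrained so both loss terms stay active; HARD constrains dissimilar
pairs to share the body part and differ only in condition. Batches are
balanced 50/50 similar/dissimilar (±1) whenever the manifest admits both
kinds. Stage preconditions (both conditions; both source tags for MEDIUM; a
body part with both conditions for HARD) raise errors naming the missing
stratum. No online hard-negative mining by embedding distance is performed;
stages are metadata strata only.

## Preprocessing and resampling

Images are resized to the model side by bilinear interpolation and intensity
mapped as (v − 0.5)/0.5 into [−1, 1]; an input already at the target size is
not resampled. Augmentation applies — to abnormal images only, and only
inside training partitions — horizontal flip (p = 0.5), rotation uniform in
±10°, and per-axis translation uniform in ±10% of the side, in that fixed
order, with bilinear resampling and zero fill.

SMOTE oversamples every minority class to the majority count: each synthetic
row is x + u(x_nn − x), u ~ U(0,1), with x_nn one of the k nearest same-class
neighbours (k = 5 for continuous-only tables). With categorical columns
(SMOTE-NC, default k = 3) the distance adds the standard mismatch penalty
(median of the numeric columns' standard deviations per differing categorical
value, implemented by a scaled one-hot embedding) and synthetic categorical
entries are the mode over the k neighbours. Original rows are preserved
verbatim.

The stratified k-fold deals each condition class round-robin to folds after
grouping by source tag and shuffling within group, so per-fold class counts
deviate from n/k by at most one sample and — whenever a (class, source)
stratum has at least k members — both source tags appear in every train and
test partition. This joint guarantee is why the splitter is implemented
directly rather than delegating to a generic class-stratified splitter.

## Post-training INT8 quantization

The PTQ driver executes, in order: fuse Conv+BN (W̃ = γW/√(σ²+ε),
b̃ = γ(b−μ)/√(σ²+ε) + β; a BatchNorm not preceded by a conv is an error),
attach pass-through observers at the model input and at every conv/linear
output (post-ReLU where a ReLU follows), run forward-only calibration
batches, derive parameters, and swap in integer kernels.

Conventions, fixed once and shared by kernels and test oracles:

- **Rounding** is half-away-from-zero everywhere "round" appears.
- **Weights**: symmetric per-channel INT8 on the output-channel axis,
  s_k = max|W_k|/127, zero-point 0, clipped to [−128, 127]; an all-zero
  channel gets a minimal positive scale.
- **Activations**: per-tensor affine; unsigned [0, 255] grid after ReLU,
  signed [−128, 127] elsewhere (input, embedding output, head logits). The
  calibrated range is first extended to include zero so the zero-point is
  always on-grid and real zero is exactly representable; the round-trip bound
  |dequant(quant(r)) − r| ≤ s/2 then holds for every in-range value.
- **Calibration**: min-max (exact observed range), percentile (defaults
  0.1/99.9 on the pooled activation sample), or KL (2048-bin source
  histogram, keep the observed minimum, exhaustively search the upper
  clipping threshold from 256 bins upward for the cut minimizing the KL
  divergence between the clipped reference distribution and its 256-level
  requantization; the full-histogram candidate reproduces min-max, so the
  KL choice is never worse than min-max in KL).
- **Kernels**: accumulate Σ (W_q − z_W)(x_q − z_x) in 32-bit integers
  (computed in int64 and checked against the int32 range), add the int32
  bias round(b/(s_W s_x)), requantize with the float multiplier
  s_W s_x / s_y per output channel, clip to the output grid, and apply ReLU
  as max(q, z_y). Max-pooling acts directly on the integer codes (max
  commutes with the monotone quantization map). Zero-padding is applied to
  the zero-point-centred codes, so padding means real 0.
- The requantization multiplier is applied in floating point rather than as
  a fixed-point integer multiplier, so bit-exactness across platforms holds
  at floating-point tolerance; no hardware-specific kernels or latency
  claims are made.

Export writes the concatenated little-endian int8 weight payload plus a JSON
sidecar (topology, shapes, per-channel scales, activation scales/zero-points,
grids, int32 biases); the loader reconstructs a runnable integer model.
Honest size accounting: INT8 reduces the weight payload 4× (1 byte vs 4),
plus small bias/scale metadata — 413.7 MB → 103.4 MB for the reference
backbone. Claims of ~40× reduction from INT8 alone are not arithmetically
reachable without additional compression (pruning, sharing), which this
package does not implement.

## Synthetic phantoms

The generator emulates the statistical structure of a two-repository fetal
ultrasound collection, not its physics (no wave propagation or probe model):

- body-part templates — concentric ellipses (brain), rib-like arcs (thorax),
  a large oval with interior structures (abdomen) — on a near-black
  background (0.03), with small geometric jitter;
- multiplicative speckle (Rayleigh-derived field, strength 0.10), smoothed
  with a σ = 0.8 Gaussian so the grain spans more than one pixel as physical
  speckle does. The correlated grain also keeps bilinear-resampled
  (augmented) and clean images statistically comparable, so augmentation
  cannot be detected from interpolation smoothing;
- abnormal frames add a bright elliptical lesion: semi-axes uniform in
  10–20% of the side, contrast +0.3, anywhere within the central anatomy;
- source textures: SRC_A adds fine speckle and a smooth vignette (a "clean
  repository" look); SRC_B adds 4-px horizontal banding, 8×8 blocky
  compression-like noise, and a +0.04 brightness lift (a "video scrape"
  look). By default normal ⇒ SRC_A and abnormal ⇒ SRC_B (the confounded
  regime); `source_mixing` flips a fraction of tags and `swap_sources`
  reverses the mapping for tag-swapped evaluation sets.

With these defaults a 1-nearest-neighbour classifier on 16×16 downsampled
pixels separates normal from abnormal at ≥ 90%, and the small CNN learns the
lesion (not just the texture) to high accuracy in minutes — the phantom's
purpose is to make downstream training targets attainable and source leakage
*detectable*, not to claim imaging realism. The artifact model for the
video-derived source is a stand-in; no quantitative artifact profile of real
scraped frames backs it. Tabular phantoms draw Gaussian class-conditional
numeric features (mean offset = `class_separation` per class step, unit
within-class SD) and class-tilted multinomial categorical columns; zero
separation yields chance-level classes by construction.

## Desk-scale experiment sizes

End-to-end runs train the small backbone (input side 32) on phantoms rendered
at side 64 — rendering above the training resolution routes every image,
augmented or not, through the same bilinear resize. The standard training run
is 15 epochs × 200 pairs at batch 32, Adam at 10⁻³ (the optimizer and batch
size are conventional choices; nothing in the method constrains them). The
quantization-fidelity experiment uses 940 normal / 60 abnormal phantoms
(the 94:6 imbalance), an 80:20 stratified mixed-source split, percentile
calibration on 8×32 training images, and a 200-image held-out evaluation.

The anti-leakage experiment trains 90 + 90 phantoms per arm at 80%
source-confounding (`source_mixing = 0.2` populates the cross-source strata
the MEDIUM stage pairs from, standing in for the few cross-source same-class
frames a real collection would contribute) and evaluates on fully
tag-swapped phantoms, comparing curriculum scheduling against naive balanced
random pairing at matched seeds and epochs. The claim verified is
directional — curriculum transfers better under a source swap — not a
magnitude.

## Known limitations

- The numpy network core is single-threaded and CPU-bound; it is sized for
  the desk-scale experiments, not for 224×224 training.
- Per-epoch pair re-sampling is with replacement at the pair level; there is
  no guarantee every image appears each epoch.
- Quantized inference dequantizes head logits before argmax; per-tensor
  affine logits preserve the argmax up to one quantization step, and ties at
  that resolution are resolved by the integer comparison.
- Phantom realism is deliberately limited (see above); results on phantoms
  bound what the pipeline can do under its stated statistical structure,
  not performance on clinical data.
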