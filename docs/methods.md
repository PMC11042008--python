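# Methods

## Problem and model

`lesionseg` segments skin lesions in dermoscopy images: given an RGB image,
predict a per-pixel probability that the pixel belongs to the lesion. The
regime that makes this hard is low contrast between lesion and surrounding
skin, irregular lesion shape, and small training sets.

The model is a dual-encoder U-shaped network. Two feature extractors run in
parallel at matching strides (4, 8, 16, 32):

- **CNN branch** — a ResNet50 topology (bottleneck residual blocks, stage
  depths 3-4-6-3, stage output channels 256/512/1024/2048 at full width),
  supplying local texture and edge features.
- **Transformer branch** — operates on 2-D feature maps throughout. Its stem
  is two **Focus slicing embeddings**: each rearranges every 2×2 pixel block
  into 4 channels (a lossless permutation, so no pixel information is
  discarded, unlike patch flattening) and then applies a 3×3 conv + batch
  norm + SiLU. Each stage applies a pre-norm block

      t ← t + SGA(LN(t));   t ← SE(t);   t ← t + MLP(LN(t))

  where LN normalises across channels per position and the MLP is a pair of
  1×1 convolutions with a 4× hidden expansion.

**SGA (spatial group attention)** replaces multi-head self-attention. The
channel axis is split into G groups; per group the global context is the
mean feature vector over all m = H·W positions, each position's significance
is its dot product with that context, the significance map is standardised
per group (zero mean, unit *population* std, with eps = 1e-5 added to the
std so constant maps give exactly zero rather than NaN), passed through a
learnable per-group affine (γ, β, initialised 1 and 0), and squashed by a
sigmoid into a (0,1) gate multiplying every channel of the group at that
position. Groups live on an explicit group axis and are re-concatenated
along channels — they are never folded into the batch axis, so batch items
cannot mix. At initialisation a spatially constant input yields a gate of
exactly 0.5 everywhere; this closed form anchors the unit tests. No scaling
is applied to the dot product before standardisation (standardisation makes
any positive rescaling a no-op anyway). Cost is linear in m, versus
quadratic for softmax attention.

**SE (squeeze-and-excitation)** recalibrates channels: z_c = spatial mean of
channel c; gates s = σ(W₂ · relu(W₁ z)) with a bottleneck of ratio r
(W₁ ∈ R^{C/r×C}, W₂ ∈ R^{C×C/r}); output channel c is s_c · u_c. The inner
activation is a rectifier and the outer a logistic — the gating reading; a
rectifier outer activation would not produce bounded gates.

**Exchange.** At every stage the same-resolution CNN features are projected
by a 1×1 conv and added to the transformer input; in the default
`bidirectional` mode the transformer output is projected back and added into
the CNN stream before its next stage (`cnn_to_trans` keeps the CNN stream
untouched, for comparison). Per stage a fused skip
`conv1×1(concat(cnn, proj(trans)))` feeds the decoder. Spatial grids are
asserted identical at every fusion point, never silently resampled. The
"passed to"/"merged" operators are projection + addition and concatenation +
1×1 conv respectively; these were open design choices.

**Decoder.** The deepest fused skip passes through the **MSF block**: four
parallel branches — a 1×1 conv (rate code 0; a literal dilation of 0 is
undefined, so code 0 is read as the 1×1 branch) and 3×3 convs at dilations
3, 6, 9 (receptive fields 7, 13, 19) — concatenated and fused by a 1×1 conv.
No global-pooling branch is added because exactly four rates are specified.
Then for stages 2→0: bilinear ×2 upsample, **channel-slice fusion** with
that stage's skip — both inputs split into two contiguous channel halves and
interleaved (skip_A, up_A, skip_B, up_B) before a 1×1 conv — and a 3×3
conv + BN + ReLU. A final bilinear ×4 upsample and 1×1 conv give one logit
channel at input resolution. Bilinear interpolation (not transposed
convolution) avoids checkerboard artifacts and parameters. Masks are
`sigmoid(logit) ≥ 0.5`, boundary included.

## Ablation variants

`cnn_only` (CNN branch only, its features as skips), `vit_only` (transformer
branch only), `no_sga` (SGA swapped for standard 4-head softmax
self-attention over the flattened stage grid — the mechanism SGA replaces;
head count is this package's choice), `no_aspp` (MSF replaced by a single
3×3 conv). All five build from `VariantSpec` and share the forward-shape,
gradient-flow and checkpoint test suites.

## Numerical engine

The network runs on the package's own reverse-mode autodiff engine
(`lesionseg.nn`): float32 numpy arrays, im2col-based convolution, explicit
backward rules per op, matrix-based bilinear resizing, an overflow-safe
logistic, and Adam. Weight init is He-normal from a process-global generator
reset by `nn.seed_all(seed)`, so model construction is bit-reproducible.
Batch norm uses population batch statistics in training and running
statistics (momentum 0.1) in eval, making inference deterministic.
Gradients are validated against central finite differences and forward
convolution against `scipy.signal.correlate2d` in the test suite.

## Defaults and tunables

| parameter | default | notes |
|---|---|---|
| input_size | 224 | must be divisible by 32 |
| SGA groups G | 8 | must divide the stage channel count |
| SGA eps | 1e-5 | added to the std, guards constant inputs |
| SE ratio r | 16 | C divisible by r enforced |
| transformer channels | 64/128/256/512 | per stage |
| fusion_mode | bidirectional | `cnn_to_trans` available |
| MSF rates | (0, 3, 6, 9) | 0 = 1×1 branch |
| optimizer / lr / batch / epochs | Adam / 1e-4 / 4 / 100 | constant lr, no schedule |
| loss | BCE + soft Dice (smooth 1.0) | headline metrics are overlap-based |
| threshold | 0.5 | boundary included |
| width_multiplier | 1.0 | scales every channel width |

`ModelConfig.reduced(w)` builds width-scaled configs for CPU-scale work and
scales the SE ratio with the width (e.g. r = 4 at w = 0.25) so the
excitation bottleneck keeps the full model's hidden width instead of
collapsing toward a single unit. A `pretrained` flag exists on the encoder
config but no ImageNet weight source is bundled, so enabling it raises; all
results here are from random init.

Scaled-down runs in the tests and the acceptance script use
width_multiplier 0.25, 96×96 inputs and lr 1e-3 — the package's own settings
for short synthetic runs (a few hundred Adam steps); the 1e-4 default is
kept for full-scale training. Problem sizes used: an 8-sample overfit run
capped at 200 steps, and a 64-train/16-test run for 15 epochs.

## Synthetic data

`synthetic_data` emulates the target regime without downloads: a skin-tone
background with low-frequency shading and fine grain; a lesion whose
boundary is an ellipse with radius modulated by a random Fourier series
(harmonics 2–5, amplitude set by `irregularity`, radius clipped ≥ 0.25 of
the ellipse so the region stays star-shaped and hence simply connected);
the mask is the exact perturbed-ellipse interior; the image darkens that
region by `contrast` (default 0.3) through a σ = 1 blurred edge plus
internal texture; optional dark Bézier-arc "hairs" occlude both regions.
Geometry resamples until the foreground fraction lies in [0.02, 0.6]. Every
sample is a pure function of its seed; dataset seeds spawn from a master
`SeedSequence`.

Augmentations follow the standard dermoscopy set: horizontal/vertical flip,
transpose (row-column flip), random rotation (±30° by default; exact
multiples of 90° use lattice rotation so pixel counts are preserved), and a
per-image linear intensity transform (gain 0.8–1.2, offset ±0.1 — the
ranges are this package's choice). Geometric ops apply identically to image
and mask (mask nearest-neighbour, so it stays binary); rotation fills
exposed corners with the border-median colour rather than black so the
corners are not a trivially learnable frame.

What the generator does *not* emulate: real dermoscopy colour distributions,
vignetting, gel bubbles, rulers/markers, multi-focal or ill-defined lesions.
Passing the synthetic pipeline therefore demonstrates that the architecture,
losses, training loop and metrics are correctly wired and can learn a
low-contrast irregular-boundary segmentation task — not clinical-grade
performance on ISIC-class data.

## Metrics

ACC = (TP+TN)/total, SE = TP/(TP+FN), SP = TN/(TN+FP), IoU = TP/(TP+FP+FN),
Dice = 2TP/(2TP+FP+FN), computed from exact integer pixel tallies. One
published rendering of the accuracy formula reads (TP+FN)/total; that
contradicts the accompanying prose definition ("correctly predicted samples
divided by all samples") and is treated as a misprint — this package
implements (TP+TN)/total. A 0/0 denominator means both masks agree the
class is absent and scores 1.0 (a NaN-skip mode exists). Dataset
aggregation is `micro` (pool counts, the headline) and `macro` (average
per-image metrics); both are reported since the convention is often left
unstated in the literature. Predictions are resized to the mask's native
resolution by nearest-neighbour before scoring.

## Degenerate inputs and tie-breaks

Constant SGA/normalisation inputs → exact zeros (eps guard); probability
exactly at threshold → foreground; empty masks → the 0/0 convention above;
odd spatial sizes are rejected by the Focus slice with the offending axis
named; channel counts not divisible by the group count, SE ratio, or the
slicing half-split are rejected with both numbers in the message.

## Known limitations

- CPU-only and single-threaded by design of the numpy engine; full-width
  224² training is possible but slow — the engine is sized for the
  reduced-width studies this repository actually runs.
- No pretrained backbone weights; results with random init at small scale
  say nothing about full-scale ISIC benchmarks.
- The exact wiring of the original dual-encoder figure (directions and
  injection points of the exchange) is not fully recoverable from prose;
  both implemented fusion modes are labelled interpretations, as are the
  slice parity order, the no_sga head count (4) and one-block-per-stage
  depth.
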