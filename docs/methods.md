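# Methods

## The detector family

All variants are anchor-based single-stage detectors with three parts:
a convolutional backbone, a PANet feature-fusion neck (top-down
upsampling path followed by a bottom-up path, C3 blocks after each
concatenation), and 1×1 prediction heads emitting 3 anchors × (5 + nc)
channels per grid cell. nc = 2 throughout: `litchi` (mature, red) and
`raw_litchi` (immature, turquoise).

**Baseline backbone** (`csp_darknet53`): the YOLOv5s version-6.0
layout at width multiple 0.5 / depth multiple 0.33 — a 6×6 stride-2
CBS stem, alternating stride-2 CBS and C3 stages (64/128/256/512
channels, C3 repeats 1/2/3/1), SPPF on the last stage. Taps at strides
8/16/32 carry 128/256/512 channels, i.e. (80×80×128), (40×40×256),
(20×20×512) at 640-px input.

**Lightweight backbone** (`shufflenet_v2`): ShuffleNet v2 1.0×
stages — stride-2 ShuBlocks followed by stride-1 ShuBlocks with
repeats 4/8/4 and output channels 116/232/464 — behind a 6×6 stride-2
stem (24 channels, matching the baseline's large first kernel) and a
3×3 stride-2 max-pool, with SPPF on the last stage. The stem width is
the standard 1.0× choice; the printed tap shapes (160×160×116),
(80×80×232), (40×40×464) at 1280-px input fix everything downstream of
the stem. Stride-1 ShuBlocks split channels in half and transform one
half by 1×1 → 3×3 depthwise → 1×1; stride-2 blocks downsample both
branches and double the channel count; every block ends with a
channel shuffle (reshape–transpose–reshape with two groups).

**CBAM**: channel attention (global max- and average-pooled
descriptors through a shared two-layer MLP with hidden width
⌊C/16⌋, summed, sigmoid) followed by spatial attention (channel-wise
max and mean maps, 7×7 convolution, sigmoid). When enabled, one CBAM
sits on each backbone tap feeding the neck — three modules, retained
in full in the cut variant because its deepest tap still seeds the
top-down pathway. The MLP and the 7×7 convolution are bias-free by
default; see "Published parameter counts" for the alternative
convention exposed as configuration.

**Head cut** (`head_cut=True`): removes the stride-32 head together
with the bottom-up limb that feeds it (the stride-2 CBS from the P4
level, its concatenation and C3). Two heads remain, at strides 8 and
16 on 116 and 232 channels — appropriate when all objects are small,
as litchi fruits are at 1280-px orchard framing.

## Parameter counting conventions

`count_parameters` reports two conventions:

* **deployed** (default): every conv+BN pair is counted folded —
  convolution weights plus one bias per output channel. This is how
  parameter totals of this model family are quoted after export-time
  BN fusion, and under it the baseline audits are exact:
  7,015,519 for the nc=2 baseline and 7,058,821 with CBAM
  (increment 2·(128²+256²+512²)/16 + 3·7·7·2 = 43,302).
* **training**: unfolded — convolution weights (no bias) plus two
  affine parameters per BN channel. The baseline then counts
  7,025,023; the difference from the deployed count, 9,504, equals
  the total BN channel count of the network.

Standalone convolutions (heads, CBAM) count their actual weights and
biases under both conventions.

### Published parameter counts for the ShuffleNet rows

Two facts about the published ablation totals are worth recording.

1. The published increment for adding CBAM on the 116/232/464 taps is
   35,382. No single CBAM construction yields both this increment and
   the 43,302 increment on the 128/256/512 taps: with the bias-free
   convention that makes 43,302 exact, hidden widths ⌊C/16⌋ give
   35,326 on the ShuffleNet taps, and no integer choice of hidden
   widths closes the 56-parameter residual. The two rows evidently
   used slightly different CBAM implementations. The package exposes
   the axes (`cbam_hidden_round`, `cam_hidden_bias`,
   `sam_batchnorm`); the "ladder" convention — hidden-layer bias in
   the channel MLP plus an unfused BN after the spatial
   convolution — reproduces the 35,382 increment exactly and is the
   default for the ShuffleNet+CBAM variants.
2. The published totals for all ShuffleNet-backbone rows sit exactly
   28,414 parameters above the construction described here, and the
   residual is invariant across those rows (it survives the head cut
   unchanged; the published uncut-minus-cut difference of 1,464,637
   equals this package's cut limb to the parameter, which is what
   pins the adapted neck widths). An extensive search over plausible
   conventions — stem widths 24–64, stage repeats, depthwise kernel
   sizes, branch-width variants, SPPF hidden/output widths, unfused
   BN accounting including buffers — produced no structure worth
   exactly 28,414 (= 2 × 14,207, a prime). The published backbone
   therefore contains an element beyond its printed description, and
   the audits of this package report the documented construction:
   3,652,337 for the ShuffleNet variant and 2,223,082 for the final
   cut variant.

## Augmentation

Geometric transforms map each box to the axis-aligned hull of its
transformed corners, clip to the canvas, and drop boxes that retain
less than 25% of their transformed area (the visibility threshold is
a package choice; it suppresses sliver boxes at crop borders).
Combo 1 applies horizontal and vertical flips each with probability
0.25 and always crops 0–20% of each dimension; combo 3 rotates by a
fixed 10° about the centre, keeping the canvas and replicating edge
pixels; combo 4 draws the Gaussian noise σ uniformly from [5, 15] on
the 8-bit scale (the recipe states only "random Gaussian noise");
combo 5 scales by 0.70–0.95 about the centre and then translates by
−15–15% (scale-then-translate order is fixed). Salt-and-pepper
corrupts exactly 2% of pixels, half to black and half to white.
All randomness flows from one seed through per-image substreams keyed
by file name (CRC32), so outputs are byte-reproducible regardless of
processing order. Offline augmentation always multiplies a training
set by exactly 6 (originals plus one output per combo). Mosaic is a
train-time 2×2 collage around a random centre; each source is resized
to fill its quadrant and boxes are remapped by the per-quadrant
affine. Mosaic is applied with a constant per-sample probability
throughout training; no late-epoch disabling policy is implemented.

## Dataset split

The 7:1:2 split computes train = ⌊0.7n⌋, val = round-half-up(0.1n),
test = remainder. This rounding reproduces the reference bookkeeping
962/138/275 at n = 1375; the ratios alone do not determine the
rounding, so it is fixed here explicitly.

## Anchors, decoding, suppression

Anchor k-means uses the 1−IoU distance on width–height pairs anchored
at the origin (Euclidean is available). Centroid updates use cluster
means; under 1−IoU the mean is a proxy for the true minimiser, so the
mean best-IoU is not guaranteed monotone per iteration (it is for the
Euclidean objective) — the run as a whole improves the fit, which is
what the tests assert. Collapsed clusters trigger a bounded restart.
Centroids are sorted by area and grouped three per head scale.

Decoding follows the v5 grid equations: centre = (2σ(t) − 0.5 +
cell)·stride, size = (2σ(t))²·anchor, confidence = objectness × class
probability. The default confidence threshold is 0.5 (detection speed
of this family is quoted at that threshold) and the NMS IoU threshold
0.45 — a convention, exposed as a flag, since no value is published.
NMS is greedy, descending-confidence, class-aware.

## Training

The loss is the unaltered v5 composite: CIoU on positive cells
(gain 0.05), BCE objectness over all cells with IoU-scored positive
targets and per-scale balance weights (4.0/1.0 for two heads,
4.0/1.0/0.4 for three), BCE classification on positives (gain 0.5).
Targets use cross-grid assignment: anchors match when
max(w/aw, aw/w, h/ah, ah/h) < 4, and the centre cell plus the two
nearest neighbour cells go positive.

Hyperparameter mapping: the published "momentum 0.937" is taken as
AdamW β₁ (the only momentum-like slot AdamW has; an SGD reading is
available via `momentum_as_beta1=False`), and the published "delay
parameter 5×10⁻³" as decoupled weight decay, applied to convolution
weights only. The cosine schedule is
lr(t) = η_min + (lr₀ − η_min)(1 + cos(πt/T_max))/2 with lr₀ = 0.01,
η_min = 2×10⁻³, T_max = 250; desk-scale runs shorten the epoch count
(and optionally T_max) without touching the endpoints, and
`last_epoch = −1` semantics correspond to starting the schedule
fresh at t = 0.

Because desk-scale runs take only tens of optimiser steps, BatchNorm
running statistics (momentum 0.03) would remain near initialisation;
after training (and before each validation pass) the running
statistics are re-estimated by averaging batch statistics over the
training set. This is a standard post-hoc recalibration and changes
no trainable weight.

## Synthetic orchard scenes

The generator emulates the statistical structure of orchard imagery:
10–100 fruits per scene, mature:immature ratio ≈ 1.28, clustered
placement (uniform cluster parents, Gaussian children), shaded
elliptical fruits with radius jitter, leafy low-frequency background,
and optional leaf/branch occluders drawn over the fruits. Annotations
cover each fruit's full pre-occlusion extent, as human annotators
label partially hidden fruit. With `cluster_size_mean ≤ 1` fruits are
placed on rejection-sampled well-spaced points — the "easy",
linearly separable regime used by the trainability checks.

What it does not model: photorealistic texture, lighting and
backlight colour shifts, motion blur, 3-D geometry, true leaf shapes.
Consequently, passing tests certify the correctness of the pipeline
(geometry, bookkeeping, metrics, optimisation) and the trainability
of the architectures on separable data; they say nothing about
accuracy on real orchard photographs.

## Desk-scale problem sizes

The package's own test and demonstration scales: smoke training uses
50 scenes of 128×128 px with 4 well-spaced fruits each, the cut
variant at 128-px input, batch 8, 5 epochs; the bookkeeping check
generates 1,375 scenes at 48×48 px. The architecture audits build
full-size models (parameter counts are resolution-independent) and
run the 1280-px tap-shape check on a single forward pass.

## Known limitations

* Convolutions run on an im2col + BLAS path in float32; training
  beyond desk scale is impractical (no GPU backend, no mixed
  precision, no EMA weights).
* Only dense and depthwise convolution groupings exist, which covers
  this family but not arbitrary group counts.
* The ShuffleNet-row published totals are not exactly reproducible
  from their printed description (see above); audits report the
  documented construction.
* The colour-threshold baseline is a corpus-sanity probe, not a
  detector for real imagery.
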