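# Methods

`stomadet` re-creates, at desk scale, an automated stomatal phenotyping
pipeline for oil-palm leaf-imprint micrographs: stomata are detected on
microscope images with a single-class, anchor-based single-shot detector
applied to overlapping tiles, duplicate boxes across tiles are merged with
non-maximum suppression (NMS), and the surviving boxes are converted into the
two phenotypes of interest — stomatal density (stomata per mm² of leaf) and
stomatal size (horizontal stoma length in µm).

Because no real oil-palm micrographs ship with the package, a synthetic-data
module generates imprint-like micrographs with exact ground truth at the
count/size statistics of four study populations. Every stage — training,
inference, stitching, evaluation and phenotyping — is exercised end to end on
that synthetic data.

## Coordinate conventions and calibration

Internally all boxes are 0-based and half-open, so a box's pixel width is
exactly `x_max − x_min` and tiling arithmetic is exact. Pascal VOC XML files
(labelImg dialect) use 1-based inclusive coordinates; conversion happens only
at the file boundary and is an exact integer map.

A micrograph carries its physical calibration as two pixel pitches,
`pitch_x = physical_width_um / width_px` and the analogous `pitch_y`. At the
default 10× geometry (1800 µm × 1400 µm at 2048 × 1536 px) these are
0.8789 µm/px and 0.9115 µm/px. They differ, and size conversion uses the x
pitch only, because stomatal size is defined as the *horizontal* end-to-end
length.

## Synthetic micrograph generator

Each image is a bright textured background (mean grayscale level ~200, a
low-frequency bilinear noise field plus white noise) on which stomata are
rendered as anti-aliased concentric ellipses: a dark guard-cell rim with a
brighter slit-shaped pore. Per image:

* the stoma count is a normal draw (per-group mean ± sd), rounded, truncated
  at zero — only summary statistics are known for the real populations, so a
  rounded truncated normal is the minimal defensible choice;
* each stoma's horizontal length in µm is a normal draw (group mean ± sd),
  floored at 30 % of the mean; its height follows from an aspect ratio drawn
  uniformly from 1.2–1.6 (width:height in physical units);
* placement is rejection sampling with a pairwise box-IoU cap of 0.05
  (stomata on the epidermis do not overlap); if a bounded retry budget is
  exhausted the image carries fewer stomata and is flagged;
* with probability 0.1 the whole image is defocus-blurred (Gaussian σ = 2 px)
  and with probability 0.1 globally brightness-shifted (×0.7–1.35),
  emulating the uneven imprint quality and microscope settings seen in real
  batches.

Stomata are rendered axis-aligned with the major axis horizontal. Real
stomata have varied orientations; fixing the orientation makes the
ground-truth horizontal box extent recover the drawn size exactly (to ±1 px
of quantization), which keeps the size phenotype well-defined. This is the
main respect (besides photorealism of the epidermis texture) in which the
generator is easier than real data: passing tests demonstrate that the
pipeline's machinery is correct and unbiased on data matching its
assumptions, not that the detector would reach the same accuracy on real
micrographs.

Group presets (per-image count mean ± sd; size mean ± sd µm): A (seedlings)
107 ± 12, 31.82 ± 2.64; B (juveniles) 200 ± 18, 34.41 ± 2.67; C (adults)
208 ± 16, 43.01 ± 3.51; D = C's biology imaged on a different microscope
(field 1589 µm × 1192 µm, darker and noisier background). The count column of
the source summary table is nominally per mm² but its accompanying text
describes per-image averages; the presets adopt the per-image reading (an
image is 2.52 mm², so the two readings differ by ~2.5×), and the phenotype
module emits both counts and densities so either convention is serviceable.

Determinism: a (config, seed) pair yields byte-identical images and ground
truth; dataset seeds are spawned from one master seed via `SeedSequence`.

## Tiling

Training uses the maximal non-overlapping grid anchored at the origin
(2048×1536 → 4×3 = 12 tiles of 512×512; right/bottom remainders discarded).
The published tile size "516 × 512" is treated as a typo for 512 × 512, which
is the only size consistent with the stated 12 tiles per image. Inference
uses an overlapping grid: origins advance by `tile − overlap` (default
overlaps 120 px horizontal, 40 px vertical) and the final origin on each axis
is clamped so the tile ends exactly at the image edge, yielding 5×4 = 20
tiles on the full geometry and guaranteeing every pixel is covered. Ground
truth is projected onto tiles by keeping boxes with ≥ 50 % of their area
inside the tile (a majority-visible stoma is learnable; a sliver is label
noise), clipping and shifting to tile coordinates.

## Augmentation

Four photometric variants expand the training set: Gaussian blur (σ = 2),
bilateral blur (window 9, σ_color 0.15, σ_spatial 3), brighten ×2 (saturating
at 255) and darken ×2 (integer floor division, so 120 → 60 exactly). All
preserve geometry, so annotations pass through bit-identically. A seeded
random fraction of tiles (default 15 %) receives all four variants; originals
are always retained, so the object count grows by
(selected-tile objects) × (number of variants).

## Detector

The detector follows the single-shot multibox recipe: a dense grid of default
boxes (anchors), per-anchor class scores and box regressions, trained with

    L = (L_c + α·L_l) / N

where `N` is the number of matched anchors, `L_c` is softmax cross-entropy
over {background, stoma} on the positives plus hard-mined negatives (3:1
negatives:positives), `L_l` is smooth-L1 on the SSD-style center/size offsets
of positive anchors, and α = 1. `N = 0` ⇒ `L = 0` (no signal in the batch).

**Backbone.** At desk scale the feature stack is a fixed multi-scale
convolutional filter bank rather than a learned deep network: after local
mean removal and global contrast normalization, a Gaussian pyramid
(σ = 1.5/3/6), difference-of-Gaussian (center-surround) channels, gradient
magnitude and local contrast are each mean-pooled at two window sizes per
8-px grid cell; dark-mass moment channels (total mass, centroid offset,
axis-wise spread over 24- and 44-px windows) give the regression head nearly
linear predictors of box center and size. The contrast normalization scale is
floored (0.05 in normalized units) so near-blank images are not amplified
into spurious structure. The trainable part is a convolutional anchor head:
one linear map shared across cells from the 24 cell features to, per anchor
shape, 2 class logits and 4 offsets. This keeps CPU training in the
tens-of-seconds range while exercising the full anchor-matching, loss,
mining, scheduling and early-stopping machinery; a deeper learned backbone
could be substituted behind the same head interface.

**Anchors.** One level at stride 8 with three shapes (36×26, 42×30, 50×36 px)
bracketing the 31.8–43.0 µm size range at the 10× calibration. An anchor is
positive when IoU with some ground truth ≥ 0.5; each ground truth also claims
its best not-yet-claimed anchor (unique best-match forcing), so every
annotated stoma trains at least one anchor.

**Optimization.** RMSprop with momentum (ρ = 0.9, µ = 0.9, ε = 10⁻³),
initial learning rate 0.003 with staircase decay ×0.95 every 100 steps,
batch size 20 tiles, L2 penalty 10⁻⁴ on head weights. Because RMSprop's
per-parameter normalization keeps step sizes large after the loss plateaus,
the raw weights oscillate; evaluation and checkpointing therefore use a
bias-corrected exponential moving average of the weights (decay 0.995),
which tracks the stable center of that oscillation. Validation mAP@0.5 is
computed every 100 steps (decode at score ≥ 0.05, decode-time NMS 0.45); the
checkpoint is updated when validation mAP improves, or when it is within a
0.005 jitter band of the best while validation loss improves — mAP@0.5
saturates early on easy synthetic data while box regression is still
converging, and the loss tiebreak keeps checkpoint selection sensitive to
localization. Training stops early after a patience budget of evaluations
without an update. Training is fully deterministic for a fixed config.

**Prediction.** Per-anchor stoma probabilities are softmax scores; boxes are
decoded from offsets, clipped to the tile, and detections below the score
threshold (operating default 0.2) are dropped.

## Stitching

Full-image detection composes: overlapping split → per-tile prediction →
shift to global coordinates → pooled greedy NMS at IoU > 0.01 (strict
comparison, ties broken by box position). The aggressive 0.01 threshold
keeps at most one box per physical stoma, which is what the counting
phenotype needs; it can also merge genuinely adjacent stomata whose boxes
overlap slightly (placement allows IoU up to 0.05), a rare, sub-percent
source of undercounting. Two optional refinements are off by default: an
edge-trim that drops detections near interior tile borders before NMS, and
box voting (score-weighted coordinate averaging over each suppression
cluster), which damps localization noise if a checkpoint's regression is
poorly converged but is unnecessary — and slightly shrink-biased — with the
EMA-stabilized training above.

## Evaluation

Two matching criteria: `overlap` (IoU > 0 — the formalization of visually
checking that a predicted box overlaps a stoma) and `iou50` (standard
benchmark matching). Matching is greedy, one-to-one, in descending score
order, largest IoU first; duplicates on an already-matched stoma are false
positives. Set-level precision/recall are means ± sd of per-image values; an
image with no stomata and no detections scores 1.0 on both so blank
negatives do not poison set means. Single-class average precision uses the
all-point interpolated area under the precision–recall staircase.

## Phenotypes and statistics

Density = count / (physical area in mm²); size = box width × x-pitch. Group
size summaries follow the assay protocol of sampling 150 stomata without
replacement from the pooled group (seeded). Groups are compared with Welch's
unequal-variance t-test computed from summary statistics
(Welch–Satterthwaite degrees of freedom, two-sided p); Welch rather than the
pooled-variance test because the group sizes and variances are unequal.

## Problem sizes and numerical choices

Default desk-scale experiments train on tiles from 10 full-size synthetic
micrographs (≈120 tiles plus augmented variants of a random 15 %, ≈2,200
stomata objects), which reaches validation mAP@0.5 ≥ 0.98 within ~500
optimizer steps; the shipped acceptance run then measures
count recovery on 55 seedling-preset images and size recovery from 150
sampled stomata over 30 adult-preset images, matching the study-set sample
sizes. Tolerances used in tests are 3 standard errors of the configured
generator distribution at the sample size used, plus a 2 % detector error
margin for counts and ±1 px worth of µm (≈0.88 µm) of rendering quantization
for sizes.

Degenerate inputs are defined rather than left to chance: empty ground truth
⇒ all-negative match with N = 0 and zero loss; empty detection lists are
valid everywhere; NMS of an empty list is empty; AP without any ground truth
is reported as undefined; zero-variance Welch comparisons return t = 0, p = 1
for equal means.

## Known limitations

* The synthetic epidermis is far easier than real nail-varnish imprints (no
  trichomes, veins, dirt, imprint bubbles or uneven focus fields); accuracy
  numbers on it are upper bounds with respect to image difficulty.
* The fixed filter-bank backbone is contrast-based and monochrome; heavily
  textured backgrounds or non-elliptical stomata would require a learned
  backbone.
* Greedy score-ordered matching in evaluation can fall short of the optimal
  assignment on rare tied configurations (observed < 2 % of ground truths on
  adversarial random instances; zero on realistic geometry).
* Stomata centered exactly on tile-overlap seams are occasionally detected
  from a clipped partial view, which slightly biases the size estimate of
  those individuals; the effect on 150-sample group means is well inside the
  quantization tolerance.
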