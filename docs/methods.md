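# Methods

This note documents the models and procedures `wmhseg` implements, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not demonstrate.

## Problem

White-matter hyperintensities (WMH) appear as bright regions on T2-FLAIR
MRI and are a biomarker of brain aging and dementia. The package implements
a two-stage approach: an *unsupervised* irregularity map (LOTS-IM) that
scores how anomalous each voxel's local texture is, and supervised
encoder/decoder networks that segment WMH from the FLAIR image, from the
irregularity map, or from both.

## LOTS-IM irregularity maps

For each axial slice and each patch size n ∈ {1, 2, 4, 8}:

1. **Source patches** tile the slice as a non-overlapping n×n grid; a source
   patch is scored iff it contains at least one brain-tissue pixel
   (brain tissue = ICV ∧ ¬CSF).
2. **Target patches** (default 2,048 per slice and size; tests use 512) are
   sampled uniformly *with replacement* from all origins whose full n×n
   window lies inside brain tissue. Sampling with replacement keeps the
   scheme well-defined on slices with few valid origins; the original
   sampling count is not documented, and 2,048 balances the stability of the
   top-100 statistic against runtime.
3. The difference between source s and target t is
   `θ·|max(s−t)| + (1−θ)·|mean(s−t)|` with θ = 0.5. The max and mean are
   taken elementwise over s−t *before* the absolute value — implemented
   literally, so for an all-negative s−t the first term is the magnitude of
   the least-negative entry. The **age value** of a source is the mean of
   its `top_m = 100` largest differences; when fewer than 100 targets exist,
   all are averaged (degenerate-input rule).
4. Each per-size age map is min–max normalised **per slice**, up-sampled
   bilinearly to slice resolution, and Gaussian-smoothed with σ = n/2 pixels
   (chosen to suppress the n×n block artifacts at each scale; the original
   smoothing width is not documented).
5. The four maps are blended as a convex combination with weights
   α, β, γ, δ = 0.65, 0.2, 0.1, 0.05 (sizes 1, 2, 4, 8).
6. The blend is **penalised** by multiplying with the FLAIR intensities, so
   only bright irregularities (the WMH signature) survive, and min–max
   normalised **globally over all brain voxels of the volume**. Outside the
   brain the map is exactly 0.

Degenerate inputs: empty-brain slices yield zero maps (logged, not errors,
because boundary slices of real scans are often empty); a constant
penalised product yields a zero map with a warning. Because the final
normalisation pins the volume maximum at 1, comparisons between scans use
region means (e.g., lesion-site means), never the raw maximum.

## Preprocessing

Intensities are standardised per slice to zero mean / unit variance over
brain-tissue voxels only, with non-brain voxels zeroed afterwards; a global
fit would be dragged toward the zero-valued background. Ground truth uses
three labels (0 non-brain, 1 non-WMH brain tissue, 2 WMH); WMH wins where
masks overlap, and WMH voxels outside brain tissue are demoted with a log
message. Training samples are 64×64 patches whose window intersects brain
tissue; by default half of the patches are forced to contain at least one
WMH voxel. The class-aware fraction is a package choice: the exact policy
that produced the original patch sets is not documented, and WMH occupy a
tiny voxel fraction, so unbiased sampling would starve the positive class.

## Architectures

All convolutions are stride-1, zero "same"-padded, cross-correlation
oriented; a CONV block is convolution → ReLU → batch normalisation; the head
is a 1×1×3 convolution with softmax trained by categorical cross-entropy.
Up-sampling is parameter-free nearest-neighbour; skips are channel
concatenations (fusion by concatenation was chosen over addition — it
preserves both branches' features and reproduces the published totals).

* **U-Net** — encoder 5×5×64, 5×5×64 | pool | 3×3×128 ×2 | pool |
  3×3×256 ×2 | pool | bottleneck 3×3×512 ×2; mirrored decoder with skip
  concatenations. 7,859,715 parameters with one input channel and
  7,861,315 with two — the 1,600 difference is exactly the first layer's
  kernel area × channels (5·5·64).
* **Saliency U-Net** — two encoder branches (raw image and regional map),
  each 5×5×64, 5×5×64 | pool | 3×3×128 ×2 | pool, concatenated to 256
  channels before the decoder (256,256 → up+skips → 128,128 → up+skips →
  64,64); both branches' features are concatenated at every skip.
  14 CONV blocks, 2,756,803 parameters.
* **Dilated Saliency U-Net** — identical layout with the four branch
  convolutions replaced by dilated 3×3 convolutions (default schedule
  1, 2, 4, 2; 1,2,2,4 and 4,2,2,1 are also predefined). A 3×3 filter at
  dilation k spans k·(n−1)+1 = 2k+1 pixels per side, so dilation itself
  adds no parameters; the 5×5→3×3 swap is what lowers the total to
  2,623,683.

**Parameter-count bookkeeping.** Batch normalisation carries 2 trainable
parameters per channel plus 2 running statistics. The published totals for
these architectures are reproduced exactly under running-stats-inclusive
counting for the U-Net family and trainable-only counting for the saliency
families; no single convention matches all four under any natural layout
(verified by exhaustive search over widths, kernels, skip wirings and
transposed-convolution upsampling). Each model therefore records its
convention, `summarize()` prints it, and `count_parameters` accepts an
explicit override.

**Depth sweep.** Saliency-family depth variants have 14, 20 or 26 CONV
blocks; each step of 6 adds one resolution level (2 blocks per branch in
the encoder + 2 decoder blocks, wired through an additional skip), with
channel widths continuing to double. The widths of the added level are a
package choice; parameter counts increase strictly with depth.

`base_width` scales all channel widths; 64 is the published configuration,
8 is the desk-scale default used in tests and examples (the shapes,
routing and losses are identical, only widths shrink).

## Training and inference

Adam (lr 1e-5 by default, batch 16), categorical cross-entropy over the
three labels with uniform class weighting. The epoch budget defaults to 50
with early stopping on validation loss (patience 10); the validation split
holds out whole scans, never patches, to avoid leakage. All batching is
seeded and training is bit-deterministic given the seed. Whole-volume
inference tiles each slice with 64×64 windows — non-overlapping when the
slice divides evenly, overlap-averaged otherwise — and takes the per-voxel
argmax of the averaged softmax.

The engine is a compact NumPy implementation (im2col convolutions with an
exact convolution-expressed backward pass, verified against numerical
differentiation end to end). It runs in float64 on a single CPU; it is
sized for desk-scale models, not for full-width training.

## Evaluation

Metrics binarise to WMH vs non-WMH (labels 0 and 1 both negative):
sensitivity TP/(TP+FN), PPV TP/(TP+FP), DSC 2TP/(2TP+FP+FN). Zero
denominators return 0 with a warning, except DSC of two empty masks, which
is 1 (perfect agreement). Per-slice and per-scan aggregation are both
supported; reports label which is used. WMH burden groups are Large
(≥ 10,000 mm³), Medium ([4,000, 10,000)), Small ([1, 4,000)) — closed on
the left as printed, so 10,000 is Large and 4,000 is Medium; volumes below
1 mm³ are ungrouped. Model comparison uses pairwise Wilcoxon rank-sum and
an overall Kruskal–Wallis test, presented with the classical rank-based
ANOVA-style table (SS, df, MS, statistic, p). The longitudinal protocol
trains on year-1 scans and reports mean DSC separately for year-2 and
year-3 scans of the same subjects; subjects without a year-1 scan are
excluded with a warning.

## Synthetic phantoms

Phantoms emulate the geometry of a 256×256×35 whole-brain FLAIR stack at
1×1×5 mm voxels (the in-plane spacing is a package default — clinical voxel
dimensions vary and are configurable). Each slice is an ellipse whose radii
shrink toward the stack ends; a thin bright rim emulates cortical
hyperintensity, two central cavities emulate ventricular CSF (scaled to a
target fraction of ICV), and lesions are ellipsoids painted at
`lesion_contrast` × the mean tissue intensity (contrast 1.7 by default,
with additive Gaussian noise at 5% of the tissue mean applied last). All
randomness flows from one seed; lesions are placed sequentially, so
increasing the lesion count extends, rather than reshuffles, the placement
sequence — this is what makes the WMH-fraction monotonicity property hold.
`phantom_suite` retargets lesion count and radius iteratively to land the
realised WMH volume inside requested burden ranges.

What the phantoms do **not** model: anatomy, bias fields, partial-volume
effects, multi-focal confluent lesion morphology, scanner noise spectra.
Passing tests therefore demonstrate algorithmic correctness (the maps
highlight what they are defined to highlight, the networks can learn the
joint FLAIR+IAM encoding, the metrics and protocols compute what they
claim) — not clinical segmentation accuracy, which requires real scans and
full-width training.

## Problem sizes

Tests and examples use 128×128×9 phantoms with 512 IAM targets, reduced
width (base 8) networks, 50 training patches and ≤ 200 epochs — sizes at
which every stage runs on one CPU in minutes while exercising the same code
paths as the full configuration.
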