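# Methods

## The problem and the pipeline

Adrenal glands occupy a few hundred to a few thousand voxels of an
abdominal CT scan, have irregular boundaries, and differ from the
tissues they touch by only a few Hounsfield units. A 2D slice-wise
segmentation model therefore produces two characteristic error types:
noisy boundaries, and occasional confident detections far from the
gland. This package implements the pipeline that addresses both without
touching the model itself, plus the evaluation machinery to quantify
the effect. Left and right glands are treated as independent binary
segmentation problems throughout; multi-organ label maps must be split
per gland id before entering the pipeline.

## Pre-processing

Intensities are clipped to a soft-tissue window `[hu_low, hu_high]`
(default (10, 60) HU) and affinely rescaled so the window maps to
[0, 1]. The order is clip → normalise → CLAHE: clipping first makes the
normalisation window well defined (the maximum a voxel can attain is
`hu_high`), and running CLAHE last lets it operate on a known [0, 1]
range. The order is a config choice, not hard-wired.

CLAHE parameters are not dictated by the windowing: defaults are clip
limit 0.01 on [0, 1] images with an 8×8 tile grid (scikit-image's
`equalize_adapthist` with `kernel_size = image_shape // tiles`). CLAHE
runs on whole slices; restricting it to a gland neighbourhood would
require localisation the pipeline does not assume.

For training only, slices without gland foreground are discarded — the
gland appears on a small fraction of slices, and a training set
dominated by empty slices drives a Jaccard-trained model toward the
all-background solution. Test volumes are always processed whole.
Augmentation adds `copies_per_slice` copies per slice (default 2, i.e.
a threefold set, matching a 1749 → 5247 slice expansion at full scale):
each copy draws a rotation uniform in ±15° and independent 50%
horizontal/vertical flips, applied identically to image and label;
images are interpolated bilinearly, labels nearest-neighbour and
re-binarised. A draw that empties the label (gland rotated out of
frame) is re-drawn up to 10 times, then skipped with a warning, so
training sets never contain empty labels.

## The slice predictor and the reference UNet

The pipeline consumes any deterministic callable from a 2D [0, 1] image
to a same-shaped probability map. The bundled reference model is a
small UNet written directly in numpy: `depth` (default 2) conv+ReLU
encoder levels with 2×2 max-pooling, channel count doubling per level
from `base_channels` (default 8); a bottleneck; a decoder with nearest
neighbour upsampling, concatenation of the equal-level encoder feature
map (the skip connection), conv+ReLU; and a 1×1 convolution with
sigmoid head. He initialisation, deterministic under a seed. The small
default size is a deliberate desk-scale choice: the pipeline, not the
backbone, is the subject here, and a depth-2/8-channel net trains on a
CPU in minutes while still learning the phantom task.

Training minimises the smoothed soft Jaccard loss

    L = 1 − (Σ p·t + ε) / (Σ p + Σ t − Σ p·t + ε),  ε = 1e-6,

with Adam (β₁ = 0.9, β₂ = 0.999) on shuffled mini-batches of 4, no
early stopping, and a hard error if any scan contributes slices to both
the training and validation sets. The default learning rate is 1e-3
(Adam convention; exposed in `TrainConfig`). Note a numerical property
of the soft Jaccard loss: the all-background prediction is a flat
region of the loss surface (gradients vanish as the sigmoid saturates),
and with tiny batches a 1e-3 step can overshoot into it and stall. The
desk-scale examples and acceptance runs therefore train at 3e-4, which
descends smoothly; at full scale with thousands of slices the default
is appropriate.

## Post-processing

**Flip TTA.** Per axial slice x: p₀ = f(x); p₁ = unflipLR(f(flipLR(x)));
p₂ = unflipUD(f(flipUD(x))); p₃ = unflipUD(unflipLR(f(flipLR(flipUD(x)))));
output (p₀+p₁+p₂+p₃)/4. "Left/right" is reversal along the column axis
of an axial slice, "up/down" along the row axis. Averaging happens in
probability space *before* thresholding, and every prediction is mapped
back to the original frame first — otherwise the average is
meaningless. Majority-voting binary masks was the alternative reading;
probability averaging is the standard one and makes the final
thresholding well defined. For a flip-equivariant predictor the four
terms are identical and TTA is exactly a no-op, which the tests assert
bit-for-bit.

**Thresholding** at 0.5 by default, with `p ≥ threshold` counted as
foreground.

**Component filtering.** Connected components are computed in 3D over
the whole scan with 26-connectivity (a gland spans contiguous slices,
so 3D connectivity is the right notion; a per-slice 2D mode and a
min-size policy are available behind config). The default policy keeps
exactly the largest component. An exact tie is broken by keeping the
component whose minimum voxel coordinate is lexicographically smallest
(scan order) — arbitrary but documented and deterministic. The filter
is idempotent, never adds voxels, and maps empty masks to empty masks.

Pipeline order: predict → TTA average → threshold → component filter.
"Before" in all reports means plain prediction + threshold; "after"
means the full chain.

## Evaluation and statistics

Dice is computed per whole scan (per patient). When prediction and
truth are both empty the score is defined as 1.0 — scans without a
gland that the model correctly leaves empty — and flagged so pooled
statistics can exclude them. Precision/recall/F1 come from voxel counts
pooled over the test set; degenerate denominators yield NaN rather than
an exception. Per-scan Dice equals the F1 of that scan's voxel
confusion counts; the suite asserts the identity on random masks.

Percentage statistics use round-half-up (12.5 → 13), applied after
rounding to 9 decimals so that values which are exact halves in decimal
arithmetic (0.10/0.80 = 12.5%) are not pushed below the tie by binary
floating-point error. The increase rate is
`100·(after − before)/before`; the bilateral average is the mean of a
model's four after-values (two glands × two datasets) in percent.

Paired *t*-tests are two-sided on d = before − after, so an improvement
yields a negative t; zero-variance differences are flagged, not raised.
The one-way ANOVA groups per-model improvements (after − before) across
datasets for each gland, testing whether improvement size depends on
the model. Both delegate to scipy.stats. The bundled benchmark table
reproduces its published derived statistics exactly, with one
documented exception: one increase-rate cell (AMOS, left gland, UNet)
prints 19 where the before-denominator formula gives 24; the package
keeps the formula, which reproduces the other 23 cells, and flags the
cell in `benchmark.py`.

## The phantom generator and noisy oracle

A phantom is a (32, 96, 96) axial stack: background HU ~ N(30, 15²),
one gland with HU ~ N(45, 8²) inside an ellipsoid (semi-axes 4×7×5
voxels, centre jittered ±2) whose radius is modulated by a smooth
low-frequency random field of relative amplitude 0.15 — small enough
that the gland remains a single connected component spanning a
contiguous slice range (asserted over 50 seeds). Gland and background
distributions overlap inside the (10, 60) window, so clipping and CLAHE
are non-trivial. Spacing is 3.0×0.8×0.8 mm, mimicking thick-slice
abdominal CT. Optional spurious bright structures appear in the image
only, at least 8 voxels (Chebyshev) from the gland bounding box.

The noisy oracle turns a truth mask into a predictor with three
controllable failure modes: Gaussian jitter (sd 0.35) on a one-voxel
band around the gland boundary; whole-slice dropout with probability
0.05; and distant blobs (expected 1.5 per scan per orientation view,
8–30 pixels, probability 0.95, centred ≥ 10 Chebyshev voxels from the
gland bounding box — far enough that keep-largest filtering is
provably correct on the phantom). Purity with orientation-dependent
noise is achieved by seeding the corruption RNG from a CRC of the
presented pixel bytes: the same input always gets the same output,
while the four flip views of a slice hash differently and get
independent noise. The oracle therefore needs the preprocessed image
volume at construction time to index slice content; it recognises
presented slices by exact byte match in any of the four orientations.

What the phantom does *not* emulate: anatomy (organs, bilateral gland
pairs), scanner physics (beam hardening, partial volume), inter-patient
variation in gland shape/size beyond jitter, and the systematic (rather
than orientation-independent) errors of a real CNN. Passing phantom
tests therefore demonstrates that the post-processing removes exactly
the error structure it targets — orientation-independent noise and
spatially detached false positives — not that any particular Dice level
transfers to clinical data.

## Problem sizes and reproducibility

The default benchmark uses 20 phantom scans of 32 slices, chosen so a
full end-to-end run completes in seconds on one CPU while leaving the
stochastic comparisons (mean Dice, pooled FP) stable across seeds;
desk-scale training uses ~140–200 augmented 96×96 slices for 10 epochs.
All randomness flows from explicit integer seeds: phantom suites spawn
per-scan seeds from a master `SeedSequence`, the oracle seeds from
content hashes XORed with its spec seed, and training shuffles with its
config seed. Reports embed a config hash and seed; rerunning a
`RunConfig` byte-identically reproduces the report JSON.

## Known limitations

The reference UNet is a minimal CNN, not a competitive backbone; the
2D-slice paradigm ignores 3D context by design (a stated limitation of
the approach it implements); resize harmonisation between scanner
matrix sizes (512² vs 768²) is left to a simple utility outside the
core pipeline; and the component filter's keep-largest policy assumes
exactly one gland instance per scan side, which is correct for adrenal
glands but not for multi-focal targets.
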