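# Methods

This note records the models, conventions and design choices behind each
stage of the pipeline, including the points where the method description
leaves genuine freedom and what was decided there.

## Illumination correction

**Model.** A darkfield frame is modeled as sparse bright structure on a
black background plus a smooth additive glow (cover-glass debris halos,
density-dependent brightness). Cells are sparse in any `wsize × wsize`
window, so the window's histogram mode estimates the local background+glow
level. Per-window modes are anchored at window centers, interpolated
bilinearly into a full-resolution mask, and subtracted with clamping at 0.

**Assumption and regime.** The window mode is only a background estimate if
the glow is near-constant within one window. Under a steep gradient the
histogram of a window smears across many bins and its mode lands wherever
the glow is locally flattest, not at the window center — no variant of the
scheme can null such a window to within ±1 level. All guarantees below are
therefore stated for glow that varies slowly at the window scale, which is
what out-of-focus halos look like.

**Parameters.**

* `wsize` (default 64 px): small against halos (σ ≳ 100 px), large against
  single blood cells (~10 px), so the mode stays background.
* `stride` (default `wsize//2`): window origin spacing. Overlapping windows
  halve the anchor distance and keep the bilinear mask's curvature error
  under one intensity level for realistic halos; `stride = wsize`
  reproduces a plain non-overlapping tiling.
* Histogram ties break toward the lowest intensity (biases toward true
  black); correction is per color channel, so colored glow is compensated
  channel by channel; output is rounded and clamped to `uint8`.

**Guarantees** (asserted by tests, in the stated regime): post-correction
window modes ≤ 1; uniform frames map to zero; a second pass changes no
pixel by more than 1 level; ordering of above-background pixels within a
window is preserved.

## Channel features

* Color: CIE 1976 L\*u\*v\* (sRGB primaries, D65 white), L\* ∈ [0, 100] —
  approximately perceptually uniform and chroma-separated, which matters
  under colored artifact glow.
* Gradient: Sobel 3×3 with replicated borders, computed on L\*. Magnitude is
  `hypot(g_col, g_row)`; orientation is `atan2(−g_row, g_col)` in [0°, 360°)
  (row axis points down), quantized to codes 0–7 at centers `45°·k`, ties
  toward the smaller code, zero gradient → code 0.
* Pyramid: 2×2 non-overlapping mean pooling (trailing odd row/column
  dropped), applied once and twice to the L/u/v grids. Gradients are
  recomputed at each level rather than pooled, so coarse orientation
  reflects coarse structure.
* Sampling: feature vectors are laid out level-major, channel-minor, with
  the anchor sample first and ring offsets in pattern order. Coarse-level
  coordinates are `⌊(anchor+offset)/scale⌋`, clamped to the grid, so border
  anchors stay usable. The default pattern places 8 offsets at radius
  `round(d/4)` and 8 at `round(d/2)` for an expected cell diameter
  `d = 40 px`, spanning cell interior to rim. The physical pixel pitch of
  the emulated camera/objective combination is not fixed here; `d` is a
  configuration parameter, not a calibrated constant.

## Boosted pixel classifier

Classical discrete AdaBoost with depth-1 stumps (default 200 rounds). The
stump search is exact: candidate thresholds are the midpoints of sorted
unique values of every feature, evaluated by cumulative weighted sums, so
training is deterministic given the sample order — ties break toward the
smaller feature index, then the smaller threshold, then polarity +1.
`ε` is clamped to `[1e−10, 1−1e−10]`; training stops early when no stump
beats chance (ε ≥ 0.5) or a stump is perfect (the ensemble cannot change
afterwards). The ensemble satisfies the exponential-loss bound
`train_error ≤ Π_t 2√(ε_t(1−ε_t))`, asserted in tests.

Training pixels are drawn uniformly without replacement: positives from
mask-true pixels (cap 2000 per image by default), negatives (3× as many)
from pixels farther than 5 px from any mask-true pixel, which keeps blurred
cell borders out of the negative class. Prediction evaluates the ensemble
stump-by-stump on shifted channel grids, which is algebraically identical to
building per-pixel feature vectors (asserted in tests) but keeps memory flat
at full-frame scale.

The decision threshold on the ensemble score defaults to 0 (ties →
non-CTC) and is exposed for trading sensitivity against specificity.

## Post-processing and evaluation

Binary opening with a discrete disk (radius 2 by default; Euclidean
`r² ≤ radius²` footprint, outside-image counts as background) removes
speck-sized false positives; note a disk opening rounds right-angle corners
of a region, so validated areas of blocky regions shrink slightly.
Components are 8-connected, labeled in raster order of first pixel, and
validated only if area **strictly** exceeds `min_area = 100 px`.

Matching to ground truth is greedy one-to-one in decreasing overlap order; a
pair is matchable when the intersection covers at least 0.25 of the smaller
object. Derived rates use the estimated-negative convention: the total
object count per frame is `avg_cells_per_image` (default 1270, an average
cell count for this kind of preparation), `TN_est = N_total − n_gt − FP`.
`compute_metrics` keeps rates at full precision; `MetricsReport.printed()`
truncates toward zero at the customary precision (2 decimals for
percentages, 4 for the estimated FP rate) — truncation, not rounding, is the
convention under which the derived rates are consistent with their integer
counts, and the package reports the arithmetic rather than chasing the
handful of published cells that disagree with their own counts.

## Synthetic scenes

The generator emulates the *statistical structure* of DF frames of spiked
blood, not their optics:

* near-black background (level 8 ± Gaussian noise σ 3);
* blood cells: bright discs (diameter 10 ± 1.5 px) with a near-flat
  interior, a brighter membrane rim and a slightly cool tint; density scales
  1270 cells per 2048×1088 camera frame to the canvas by area (~150 on
  512×512); blood–blood contact is allowed;
* tumor cells: larger (diameter 40 ± 4 px), irregular contour (low-order
  Fourier modulation of the radius, bounded at ±35 %), brighter rim, warm
  tint, and strong per-channel interior speckle (σ 35 ×
  `tumor_texture_contrast`) — the interior-texture contrast against smooth
  blood cells is the separability property the learning pipeline relies on;
* per-cell tint jitter (×U(0.92, 1.08) per channel), so hue is informative
  but not a clean per-pixel label;
* halos: additive 2-D Gaussians (σ ∈ [100, 160] px, amplitude ∈ [25, 45]),
  deliberately in the slowly-varying regime the illumination model assumes;
* ground truth is true exactly on tumor pixels; tumor cells are kept
  disjoint from each other and from blood cells by bounded rejection
  sampling, so the mask has exactly `n_tumor` components.

What passing tests on these scenes shows: the pipeline's stages compose
correctly and can learn and recover cell-scale textured objects at realistic
densities and under artifact glow. What it does not show: performance on
real DF data — real cells have no published intensity/texture statistics to
emulate, white-cell subtypes, debris and focus variation are absent, and the
synthetic separability is by construction cleaner than biology.

## Problem sizes and numerical choices

The end-to-end experiment used by the tests and the acceptance script runs
30 frames (512×512, 3–5 tumor cells each, 70/30 split by image), 200
boosting rounds, and 300 positive samples per training image (the library
default cap of 2000 is unchanged) — sizes chosen to keep the exact stump
search at desk scale while leaving every default threshold (score 0, opening
radius 2, area 100, overlap 0.25) untouched.

All randomness flows from explicit integer seeds (`numpy` `SeedSequence`,
per-image spawn keys; dataset seeds are `seed + i`), making generation,
sampling, training and evaluation bit-reproducible. 16-bit inputs are
min/max-rescaled to 8 bits on load because the histogram logic assumes 256
levels. Degenerate inputs fail loudly: empty histogram windows, masks of
mismatched shape, single-class training sets, models without a version
field, and evaluation without ground-truth objects all raise with a message
naming the offender.

## Known limitations

* The illumination model cannot null glow that is steep at the window scale
  (see regime note above); such frames need a smaller `wsize` with the
  attendant risk of cell-scale modes.
* The area rule (> 100 px) and the default ring pattern assume roughly
  cell-sized detections at full resolution; heavily clustered tumor cells
  merge into one component (no watershed splitting).
* Estimated specificity/accuracy inherit the 1270-cells-per-frame
  convention; they are estimates, not measurements.
* Shape-based re-scoring (circularity, texture models) and cascade/soft
  boosting variants are out of scope.
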