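# Methods

## Model and assumptions

The detector treats focus-point localization as adaptive clustering on a
binary tissue mask. Its assumptions are:

* positively stained (Ki-67) tissue is *dark* in the thumbnail, so the
  tissue class after Otsu thresholding is the one at or below the threshold;
* illumination varies smoothly across the slide, so thresholding is done per
  partition (six partitions by default) rather than globally;
* a hot spot is any region whose local tissue-pixel density inside a
  fixed-size window exceeds a threshold — shape is deliberately ignored, so
  every detection is a same-size box a pathologist can zoom into directly;
* debris (small tissue fragments spread during slide preparation) appears as
  very low-density responses and can be consumed silently.

Randomness enters only through the choice of seed pixels. Because every
accepted or discarded box removes its pixels from the search set Ω, the
expected number of boxes scales with the tissue area, not with a preset k.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `box_size` | 150 (focus) / 40 (bounding) | px | candidate window side |
| `accept_threshold` (T_r) | 0.15 / 0.10 | density fraction | minimum density of an accepted box |
| `tier_cutoffs` | 0.15, 0.30, 0.50, 0.75 | density fraction | black/green/blue/red priority scale, closed at the lower edge |
| `discard_threshold` | 0.10 | density fraction | below this, pixels are debris: consumed, no region |
| `t_min_fraction` | 0.15 | fraction of box area | stop when \|Ω\| < 0.15·box²; a perfect box could no longer reach the lowest tier |
| `max_failures` | 100 | count | consecutive non-acceptances tolerated per partition |
| `partition_rows/cols` | auto (2×3 landscape, 3×2 portrait) | — | six near-square partitions |
| `clahe_tiles`, `clahe_clip` | (8, 8), 0.01 | — | CLAHE locality and clipping |

Two resolved ambiguities are worth recording. First, the boundary between
"reject" and "discard": densities in [0.10, 0.15) are plain rejects (a
failure, nothing consumed); only densities below 0.10 trigger debris
removal. Both thresholds are configurable, so collapsing them (as the
bounding mode does, with both at 0.10) is a config choice, not a code path.
Second, the failure budget stops a partition when the count of consecutive
failures *reaches* `max_failures`; with that convention a run obeys the
bound `iterations ≤ (accepts + discards) + max_failures · (accepts + 1)`,
which the test suite asserts.

## Numerical and geometric conventions

* Coordinates are (row, col), 0-based; extents are half-open. An
  even-sized box spans `(s−1)//2` pixels before and `s//2` after the center,
  so a 150 box clipped at the image corner is 76 × 76.
* Boxes are clipped to the partition and the density denominator is the
  clipped area (configurable: out-of-bounds pixels may instead count as
  background). Clipping avoids phantom background deflating edge densities.
* Densities inside a run are computed against the *live* Ω, so a box
  overlapping previously consumed pixels is scored on what remains. This is
  what makes the pixel-conservation invariant exact: initial |Ω| = final
  |Ω| + Σ removed.
* Otsu's threshold is taken from scikit-image and verified in the tests
  against exhaustive minimization of the weighted intraclass variance over
  all 256 candidate levels; a constant image raises a degenerate-input
  error (the pipeline maps such partitions to empty masks).
* Per-partition RNG streams are spawned from one seed sequence, so results
  are reproducible and independent of partition processing order.
* k-means uses Lloyd iterations from k distinct random data points with the
  squared-error objective recorded each round; an emptied cluster is
  re-seeded on the farthest point. Fuzzy c-means uses the standard
  alternating updates with fuzzifier m = 2, row-normalized memberships, and
  full membership for a point coincident with a center. Both stop on a
  movement/membership tolerance (1e-4 / 1e-5) or an iteration cap.

## The synthetic benchmark

`rppd.synthetic` generates the study conditions used throughout the tests:
a 1032 × 1380 canvas (one-ninth the pixel count of the 4140 × 3096
thumbnails the defaults are sized for; the full size runs in the end-to-end
test), five disjoint planted rectangles of side 200–280 px with internal
Bernoulli density 0.8–0.95, background scatter at fraction 0.01, rendered
as brown stain (≈ RGB 110/72/45 ± jitter) on a near-white ground under a
smooth multiplicative illumination field of strength 0.15. The bounding
scenario uses a single elliptical blob (density 0.95) with scatter 0.002 —
scanning slides carry little debris. Segmentation recovers the planted mask
essentially exactly under these conditions (round-trip Jaccard ≥ 0.9 is
asserted; in practice ≈ 1.0), so pipeline tests exercise the search rather
than the thresholding.

What the generator does *not* emulate: cell-level texture, stain intensity
gradients within a hot spot, tissue folds, air bubbles and out-of-focus
blur. Passing these tests therefore shows the search behaves as specified
on masks with known structure; it does not certify clinical performance,
where segmentation errors and preparation artifacts dominate the
false-positive budget.

## False positives are a matter of definition

With T_r = 0.15, a box may be legitimately accepted while most of its area
hangs off a hot spot — e.g. a box centered at a planted region's corner has
ground-truth overlap ≈ 0.25 and is accepted at black tier. Under a
majority-overlap correctness rule (overlap ≥ 0.5) such boxes count as false
positives, and on the default five-region slides they occur on essentially
every run (measured AFPR ≈ 14–16% under that rule). Under the off-tissue
rule — a false positive is a box whose true-tissue overlap is below T_r,
matching the idea of a detection *outside the tissue borders* — an accepted
box can never be a false positive, because its ground-truth overlap is at
least its live density. Both figures are computed and reported; comparisons
with the clustering baselines use the off-tissue rule, under which the
adaptive search scores 0% while centroid-based baselines place some cluster
centers between tissue masses and score well above it.

## Known limitations

* No overlap suppression beyond pixel consumption: accepted boxes may
  overlap in area (not in consumed tissue), and late boxes in a consumed
  neighborhood carry lower tiers than the underlying tissue would suggest.
* The number of detections depends on the draw order; only the statistics
  (recovery, conservation, termination) are guaranteed, not the exact box
  set.
* Single-resolution thumbnails only: no pyramidal slide formats, no stain
  deconvolution, no color normalization.
* The fixed-size box is a feature for the downstream zoom workflow but a
  poor fit for long, thin tissue structures, which are covered by several
  partially filled boxes.
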