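# Methods

This note records the models and procedures `celldet` implements, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic generator does and does not emulate.

## Geometry

Boxes are axis-aligned rectangles on a 0-based, half-open pixel lattice:
`[x_min, x_max) × [y_min, y_max)`, area `(x_max − x_min)(y_max − y_min)`.
The half-open convention avoids the classic ±1 area bugs and makes the
continuous Jaccard index agree exactly with integer pixel-membership
counting for integer-coordinate boxes, which the test suite uses as an
independent oracle. Jaccard is computed on continuous box geometry, never on
rasterized masks.

Pyramid-level mapping multiplies (low→high) or divides (high→low) by the
per-axis scale factors (high-mag pixels per low-mag pixel, ≥ 1). The round
trip is bit-exact for integer-coordinate boxes at integer scales; for
fractional coordinates at non-power-of-two scales IEEE rounding limits the
guarantee to well under one pixel per coordinate. ROIs found at low
magnification are accepted as boxes; no margin is added around them (none is
specified anywhere, and a margin is trivially applied by the caller).

Tile grids cover a `w × h` image with `⌈w/q⌉·⌈h/q⌉` tiles in row-major
order; edge tiles are clipped so the tiles partition the image area exactly.

## Cascade sampling and the dual-layer negative filter

Stage thresholds are φ_z = φ₁ + (z−1)ρ with defaults φ₁ = 0.5, ρ = 0.1,
Z = 3 and the second-layer threshold φ_i = 0.1. A candidate's overlap ϖ is
its maximum Jaccard over all annotations regardless of class (class-aware
matching at the sampling stage is not part of the design); ties go to the
lowest annotation index. All threshold comparisons are boundary-inclusive
(ϖ ≥ φ).

The dual-layer filter is applied to the final stage only: stage-Z negatives
with ϖ ≥ φ_i become refined negatives, the rest are ignored (weight 0).
A `refine_all_stages` switch applies it at every stage for ablation.
The rationale: under partial annotation, a negative with *some* overlap to
an annotated cell is genuinely hard background, while a negative with almost
no overlap to any annotation is as likely to be an unlabeled cell as true
background — training on it teaches the model that cells are background.

The exact soft-sampling weight function is deliberately pluggable; the
default is linear in overlap, `w(ϖ) = w_min + (1 − w_min)·ϖ/φ₁` clipped to
`[w_min, 1]` with floor `w_min = 0.1`. It satisfies the intended behavior —
everything non-ignored contributes, with attention growing with overlap —
while remaining replaceable by any `(overlap, score) → (0, 1]` map. Soft
weights are applied at proposal level and the dual-layer filter at the
final-stage head; weights are emitted for an external trainer (no gradient
computation here).

## Suppression

Detections carry a per-class probability vector; suppression uses only the
argmax class and its probability (the full vector is carried through for
reporting). After the confidence cut ϱ = 0.5 (inclusive), SCNMS performs
greedy descending-score selection independently within each class; MCNMS
performs one greedy pass over all classes jointly. A detection is suppressed
iff its Jaccard with an already-kept (same-class for SCNMS, any-class for
MCNMS) detection is ≥ η (default 0.3). Ties in score are broken toward the
smaller input index, making results deterministic. Greedy star-shaped
selection is used (each kept box suppresses its own conflicts); suppression
does not propagate through suppressed boxes.

Consequences that are theorems of this construction, asserted in tests:
MCNMS output has no two kept boxes at Jaccard ≥ η (the
contradiction-freedom guarantee); both passes are idempotent; kept and
suppressed partition the input.

One plausible-looking law is *not* a theorem: the MCNMS kept set is not
always contained in the SCNMS kept set. In a chain configuration — a
top-scoring class-1 box overlapping a class-0 runner-up which overlaps a
lower-scoring class-0 box, with no direct conflict between the first and
third — the joint pass removes the runner-up and thereby revives the third
box, which the per-class pass suppresses. The unit suite pins an explicit
counterexample and verifies that every observed inclusion violation is of
exactly this chain form. On realistic post-threshold detection fields (cells
with bounded mutual overlap) chains are rare, and the inclusion holds for
the overwhelming majority of random instances.

A brute-force oracle (global/per-class max extraction with conflict
deletion, overlap areas computed with shapely rather than the package's own
box algebra) verifies both passes on instances of ≤ 12 boxes.

## Augmentation and normalization

A tile is selected for augmentation iff its positive fraction — the area of
the union of annotation boxes intersected with the tile, over the tile area
— is > 0. Annotation *boxes* (not cell masks) define the positive region;
overlapping annotations are not double-counted (shapely union).

The default operation set emits, independently per tile (not composed):
eight rotations (5°, 10°, 15°, 20°, 25°, 90°, 180°, 270°), horizontal and
vertical mirror flips, and `n_jitter = 2` photometric copies. Jitter draws a
multiplicative contrast factor in [0.8, 1.2] (scaling deviation from the
mean intensity), a multiplicative saturation factor in [0.8, 1.2] (HSV S
channel), and an additive brightness offset in [−0.125, +0.125] on the
[0, 1] scale; outputs are clipped to [0, 1]. Right-angle rotations are exact
(`np.rot90`); small-angle rotations interpolate and fill exposed corners
with the per-channel median of the patch, a neutral background estimate.
All jitter randomness flows from the spec's seed, so outputs are
bit-reproducible. A compose mode (product set) is intentionally not
implemented in the first release; copies are emitted independently.

Normalization is histogram specification: per channel, each pixel is mapped
through the image's empirical CDF (mid-rank estimate, ties averaged so equal
inputs map equally) and then through the inverse reference CDF via linear
interpolation on a 256-level grid. A constant channel carries no
distributional information and maps to the reference median. The packaged
default reference is a *synthetic* natural-image-like distribution (smooth
unimodal Beta-shaped per-channel CDFs, red slightly brighter than green than
blue), in closed form with no download; users with a reference corpus fit
their own with `fit_reference_histogram`. Reference CDFs serialize as a TSV
level→cumulative-probability table.

## Adaptive schedule

With I images of w × h pixels tiled at q, the data contains
N = I·⌈w/q⌉·⌈h/q⌉ patches (ceiling division, matching the tiling module;
augmentation excluded). The multiplier is r(Λ) = 1 − ⌊Λ/ϱ_lr⌋·α, clamped at
0 because the raw expression goes negative once Λ exceeds ϱ_lr/α. The step
length is ϱ_lr = N/α by default — the reading under which the decay horizon
grows with the data size, which is the stated point of the mechanism; the
alternative reading ϱ_lr = αN is available via
`interpretation="proportional"`. α defaults to 10%. A fixed milestone
baseline (multiplicative 10% cuts at 160k and 240k iterations) is provided
for comparison; "reducing by 10%" is implemented multiplicatively
(0.9 per milestone).

## Evaluation and clinical reporting

Matching is greedy by descending detection score, one-to-one, at IoU ≥ 0.5
by default (the common detection convention; the protocol is configurable).
Class-agnostic matching measures localization ("detection" metrics, TP
counted under the annotation's class); class-required matching measures
classification. Per-class recall = TP/(TP+FN), precision = TP/(TP+FP), F1
harmonic; zero-denominator metrics are reported as NaN and excluded from the
macro average. Per-class accuracy is (TP+TN)/|universe| with the universe
defined as all evaluated objects (every annotation plus every unmatched
detection) — an explicit convention, since per-class accuracy has no
canonical denominator in detection. PR-AUC is the area under the
interpolated precision envelope over a score sweep. Confusion matrices are
row-normalized percentages over matched pairs.

Cohen's κ = (p_o − p_e)/(1 − p_e) with chance agreement from marginal
products, computed directly from the formula so the degenerate case (both
raters constant and identical, p_e = 1) can be defined as κ = 1 with a
warning; the implementation is cross-checked against
`sklearn.metrics.cohen_kappa_score` in tests. Interpretation bands use the
conventional cut points with inclusive upper bounds: ≤ 0.20 poor, ≤ 0.40
fair, ≤ 0.60 moderate, ≤ 0.80 good, otherwise excellent (so κ = 0.8 is
"good").

The NDC report forms per-class percentages over all counted cells (summing
to 100 whenever the total is positive), supports an exclusion list for
non-countable categories (e.g. megakaryocytes), and flags adequacy at the
≥ 500-cell rule, boundary inclusive.

## Synthetic fields

The simulator emulates the *statistics* that the sampling and suppression
machinery cares about, at sizes chosen so the full suite runs in well under
a minute on one CPU:

- 512 × 512 fields with 40 elliptical cells of 5 classes, radii 8–16 px,
  placed by rejection sampling with pairwise true-box Jaccard < 0.3
  (touching, rarely heavily overlapping cells);
- a controllable unlabeled fraction u: `round((1−u)·n)` cells are annotated,
  the rest are true objects invisible to the sampler — the partial-annotation
  failure mode itself;
- 3 jittered proposals per true object (Gaussian translation/scale noise at
  35% of the radius) with scores 0.15 + 0.75·ϖ + N(0, 0.08) clipped to
  (0, 1), giving a score–overlap rank correlation around 0.85, plus 20 pure
  background proposals with low scores;
- one detection per true object with a Dirichlet probability vector
  concentrated on the true class (≈95% expected mass, emulating a
  well-trained classifier), plus a Poisson(1) count of diffuse spurious
  detections that fall below the ϱ = 0.5 cut;
- a two-level variant that renders a low-magnification overview and per-ROI
  high-magnification crops at an integer scale factor, with cells split
  across ROIs in proportion to area.

All randomness flows from a single seed through one `numpy` generator, so
identical specs reproduce bit-identical fields.

What the generator does **not** emulate: stain variation, cell morphology
and texture (cells are flat ellipses), lipid artifacts, annotator bias in
*which* cells get labeled (the unlabeled subset is chosen uniformly), and
detector-correlated errors (proposal noise is independent across objects).
Passing tests therefore demonstrate the correctness and the directional
behavior of the algorithms (e.g. that the dual-layer filter strictly reduces
contamination of the negative pool by unlabeled objects — measured at
≈ 4% vs ≈ 34% pooled over 50 half-annotated fields), not performance
numbers transferable to real whole-slide images.

## Numerical conventions and degenerate inputs

- Empty or inverted boxes are rejected at construction; operations are total
  on valid inputs.
- All threshold comparisons printed as ≥ are implemented inclusive.
- Score ties everywhere break toward the smaller input index.
- Empty candidate/detection/annotation lists yield empty, well-typed
  results, never errors; genuinely contradictory configuration (thresholds
  ≥ 1, η or ϱ outside [0, 1], tile larger than image, scale < 1) raises
  `ValueError` at construction.
- The simulator raises after bounded retries when the requested cells cannot
  be placed at the overlap bound.

## Known limitations

- The sampler emits labels and weights; it does not train anything, so the
  benefit of the dual-layer filter is demonstrated on the negative-pool
  contamination statistic, not on a trained detector's recall.
- Histogram specification operates per channel; no stain-deconvolution
  (Macenko/Vahadane) normalization is provided.
- Per-class accuracy and PR-AUC follow documented local conventions and are
  not comparable across tools that define them differently.
- The MCNMS⊆SCNMS inclusion fails in rare chain configurations, as analyzed
  above; downstream code must not rely on it.
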