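# Methods

This note documents the models, algorithms and design choices behind
seedleaf: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and the numerical
conventions that make results reproducible to the byte.

## Coordinate and raster conventions

All rasters use (row, col) indexing, 0-based, origin at the top-left;
wherever a formula is written in (x, y), x is the column and y the row.
Pixel centers sit at integer coordinates.  Normalized polygon
coordinates denormalize under the pixel-center convention
(`x_px = x_norm · width − 0.5`), stated once here and applied everywhere
(annotation rasterization, polygon export from the generator).

## Classical operators (`seedleaf.imops`)

**Morphology.**  Erosion/dilation are plain min/max over a structuring
element; opening and closing are their compositions.  The default
element is the 3×3 square (8-connected) — the smallest element that
removes single-pixel noise and bridges single-pixel cracks at cotyledon
scale; size is configurable.  Border policy: out-of-bounds samples are
*ignored* by default (erosion effectively pads +∞, dilation −∞), so
shapes touching the crop boundary are not artificially eroded; a
`padding="zero"` mode treats the outside as background.  On binary
input, opening is anti-extensive, closing extensive, both idempotent —
these algebraic identities are tested as exact raster equalities.

**Otsu binarization.**  The threshold maximizes the between-class
variance `σ_B²(t) = w0·w1·(μ0 − μ1)²` by exhaustive scan over all
histogram levels.  Integer-valued images are histogrammed at their
native levels (so adding a constant c to every pixel shifts t* by
exactly c); non-integer images are linearly rescaled onto 256 levels
first.  Tie-break: the smallest maximizing t.  A constant image has no
valid threshold and raises a degenerate-input error rather than
guessing.

**Canny.**  Gradients come from 3×3 Sobel kernels on the
Gaussian-smoothed image (σ = 1 px default; replicated borders so
constant images have exactly zero gradient).  Non-maximum suppression
quantizes the orientation into 4 sectors; of two equal-magnitude
neighbors along the gradient the lower-(row, col) one survives, keeping
ridges one pixel wide.  The double thresholds default to
`high = Otsu(gradient-magnitude histogram)`, `low = 0.5·high` — a
parameter-free default that adapts to scene contrast — with both values
overridable.  Hysteresis keeps weak-edge components 8-connected to at
least one strong pixel.

**Distance transform.**  Exact Euclidean, via the two-pass parabolic
lower-envelope algorithm (per-column 1-D distances, then a per-row
lower envelope over squared distances).  Exactness matters because
watershed markers are defined relative to true distance maxima; a
chamfer approximation would bias marker placement.  The brute-force
nearest-background minimization is retained as a test oracle and must
agree to 1e-9.

**Watershed.**  Meyer-style priority flood on the negated distance map
with 8-connectivity.  Contested equal-priority pixels are pushed with a
secondary key (the source pixel's distance, then the label id, then
insertion order), which implements "assign to the adjacent label with
the larger distance value, ties to the lower label" and makes the
foreground partition total: the per-label pixel counts always sum to
the foreground count, so downstream areas are conserved.

**Instance splitting.**  Markers are connected components of
`{D ≥ f · max D}` computed *per 8-connected blob* (default
`f = 0.4`), which normalizes the rule across leaves of different sizes;
fragments below `min_area = 20 px` are discarded and labels are
renumbered consecutively in deterministic component order.  The rule
separates *barely touching* leaves: it requires the contact neck to be
thinner than `f` times the lobe's inscribed radius.  Two limits follow,
both verified empirically: (i) heavily interpenetrating shapes (e.g.
disks of radius 12 px whose centers are 16 px apart, neck ≈ 0.75·r)
are *not* split by the fraction rule — they need markers placed at the
distance maxima directly, which `watershed` supports; (ii) splitting
degrades for leaves so small that the ~1 px bridge created by closing
at a tangency is comparable to `f · max D` (below roughly 1000 px per
leaf with the 3×3 element).

## Geometry and calibration (`seedleaf.quantify`)

Area is the per-instance pixel count — a discrete region integral —
not a polygon area from the contour; this choice makes "sum of instance
areas = foreground area" an exact invariant under the watershed's total
partition.  Contours (Moore boundary tracing, clockwise, with Jacob's
stopping criterion) serve the perimeter and visualization.  Perimeter
sums 1 per axis step and √2 per diagonal along the closed ring; on
digital disks of radius 30 px this is within ~5% of the analytic
circumference, and a single-pixel instance has zero perimeter by
convention.

Calibration stores `Δx = Lx/w` and `Δy = Ly/h` as exact
`fractions.Fraction` ratios.  The familiar 0.0167 cm/px of a 25 cm tray
at 1500 px is a 4-decimal display rounding of 25/1500; squaring the
rounded value instead of the ratio would bias every area by ≈0.5%, so
rounding happens only at display time and the full-tray area is exactly
625 cm².  Perimeter converts with Δx alone (square-pixel assumption); a
warning is issued when Δx ≠ Δy.

## Per-frame pipeline (`seedleaf.pipeline`)

Step order: rasterize/load mask → refine → background removal → Canny →
watershed splitting → contours → measurement → overlay.  Edges feed the
visualization and boundary cross-checks; *areas always come from the
labeled region*, because the edge map is not guaranteed to close.
Frames with zero detections produce a valid empty result (time series
keep their cadence).  The overlay uses a fixed 8-color palette,
α = 0.4 tint, contour polylines and a per-instance
"id: area cm² / perim cm" caption rendered with PIL's built-in bitmap
font, so identical inputs give byte-identical PNGs.

`fallback_segment` is a model-free segmenter — excess-green index
(2G − R − B), Otsu, morphological refinement — that lets the pipeline
run end-to-end on raw color images when no detector output exists.  On
constant-index images it returns all-foreground when the index is
green-dominant and empty otherwise.

## Tracking and growth rates (`seedleaf.tracking`)

Association is greedy nearest-centroid between consecutive frames,
gated at `max_displacement = 30 px` (tray scale 1500 px; germinating
seedlings barely move), ties broken by larger bbox overlap then lower
instance id.  A track that misses a frame ends; ids are never reused
and tracks never merge (leaves do not exchange identities in this
assay).  `min_track_length` defaults to 1 (keep everything).

RGR is the percent area change per sampling interval,
`100·(A_k − A_{k−1})/A_{k−1}`, reported at the interval end.  The time
base is explicit configuration: per-interval by default, with a
per-hour normalization option, since a quoted peak rate is meaningless
without its interval.  RGR is scale-free — identical on pixel or
physical areas — and an interval whose preceding area is zero is
flagged NaN, never dropped.

## Synthetic tray generator (`seedleaf.synthdata`)

The generator emulates the acquisition setup the package targets: a
25 cm × 25 cm tray imaged top-down at 1500 × 1500 px, seeds in a 6 × 6
grid, each producing a cotyledon pair (two leaf instances), frames on a
fixed cadence from sowing.  Each leaf is a rotated union of two ellipse
lobes (aspect 0.62, lobe centers offset 0.33·a along the axis) — five
parameters that reproduce the relevant failure mode (partial
overlap/adhesion of neighboring leaves) without photorealism.  The
rendered pixel count is matched to the requested area by bisection on
the lobe scale (within ~1% for leaves of a few hundred px and better
for larger ones) and the *exact* rasterized count is recorded as ground
truth.  Leaves smaller than 30 px are treated as not yet emerged.

Growth follows per-leaf logistic profiles
`A(t) = A_max / (1 + e^{−k (t − t0)})` for t past emergence — the
"early rapid enlargement, then gradual slowing" pattern of germinating
cotyledons.  Defaults: `A_max` ~ U(0.5, 1.0) cm² (realistic cotyledon
areas that also fit a 6×6 grid cell), `k` ~ U(0.08, 0.16) h⁻¹,
inflection 75–95 h, emergence 48–60 h.  In a time series each leaf is
anchored at the pair offset of its largest rendered size, so growth
changes area while centroids stay put (≤ ~1.5 px random jitter per
frame), matching how attached cotyledons behave and keeping the
tracking gate meaningful.  "Overlapping" pairs interpenetrate by 0.5 px
at the tips — barely touching — which is the regime the watershed
marker rule is designed for.

Photometrics: flat gray tray with mild vignetting, small brown seed
disks as distractors for the vegetation-index fallback, flat per-leaf
greens.  Augmentations (exposure gain/gamma, hue/saturation jitter,
grayscale, Gaussian/motion blur, additive noise) apply in a fixed
documented order and never touch geometry, so instance ground truth
remains valid for augmented images.  All randomness derives from the
single scene seed through named substreams (layout, shape, photometry,
per-frame jitter); identical specs give byte-identical scenes.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: true leaf morphology (serration, petioles,
curling), specular highlights and shadows, soil/substrate texture,
out-of-plane leaf pose, detector-characteristic mask errors (it renders
geometrically exact masks), or leaves crossing cell boundaries.
Real-data performance additionally depends on the upstream detector's
mask quality, which is outside this package's scope.

## Evaluation utilities (`seedleaf.metrics`)

Matching is greedy in descending prediction score, one ground truth per
prediction, over mask IoU.  AP integrates the precision–recall
staircase with all-points interpolation (precision envelope), which is
exact for finite tables and invariant to monotone score transforms;
mAP50–95 averages the ten IoU thresholds 0.5–0.95.  With a single
class, the class-mean degenerates to that class's AP; the code keeps
the general form.

The conv-layer counters follow the commonly printed formulas verbatim:
`Params = Cin·K²·Cout` (weights only) and
`FLOPs = 2·H·W·(Cin·K² + 1)·Cout` (the +1 being the bias).  The two are
deliberately inconsistent about the bias term — the first excludes what
the second includes — and are kept as-is rather than reconciled, since
they are reporting conventions, not a model.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on 8×8–30×30 rasters against brute-force
oracles (double-loop morphology, exhaustive Otsu scans,
nearest-background distance minimization).  Scene-level tests use 2×2
seed grids on 400–500 px trays with leaf areas at the full-assay pixel
scale (~2880 px ≈ 0.8 cm² at the reference calibration), because
morphological behavior depends on absolute pixel scale.  The end-to-end
check renders one full 36-seed, 1500 px tray; the tracking experiment
renders 16 frames of 6 leaves at 4 h spacing over 60–120 h on a
750 × 500 px tray (calibrated at 0.02 cm/px).  These sizes keep the
whole suite around fifteen seconds while exercising every code path at
representative scales.

## Known limitations

* The watershed marker rule cannot split shapes whose contact neck is
  thicker than `marker_fraction` of the inscribed radius (deep
  interpenetration); marker placement at distance maxima is the
  fallback for such cases.
* Perimeter discretization overestimates smooth boundaries by a few
  percent (√2-weighted chain length); no sub-pixel correction is
  attempted.
* The tracker does not bridge detection gaps or handle merges; a missed
  frame terminates the track by design.
* The excess-green fallback segmenter assumes green foliage on a
  non-green background and is not a substitute for a trained detector
  on real imagery.
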