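# Methods

This note documents the models, conventions and numerical choices behind
`vesselquant`, and what its synthetic benchmarks do and do not demonstrate
about real slide data.

## Physical conventions

All analysis is carried out in physical units (µm, µm²). A raster is tied
to a calibration `microns_per_pixel` (default 0.137 µm/px, a typical 40×
scanner pixel size); areas scale with its square. Image coordinates are
0-based, row-major, y-down, and a pixel `(i, j)` contributes its centre at
`((j + 0.5)s, (i + 0.5)s)`. This pixel-centre convention is used everywhere
a raster meets continuous geometry: instance centroids, point-in-ROI
membership of pixels, and ROI restriction of pixel confusion counts, so the
instance-level and pixel-level rules can never disagree about what "inside
the ROI" means.

The **equivalent radius** of an object of area A is r = √(A/π), the radius
of the circle of equal area. It is the length scale used by both the NMS
gate and the matching gates, which makes those gates scale-adaptive: large
vessels tolerate proportionally larger centroid offsets.

**Perimeter estimation.** The boundary length of a rasterized object is
estimated with the Crofton formula over 4 directions
(`skimage.measure.perimeter_crofton`). Raw boundary tracing of a binary
grid (marching squares on a 0/1 mask, or boundary-pixel counting)
systematically overestimates smooth perimeters by the staircase effect
(~6% for discs); the Crofton estimator is deterministic and lands within
~2% of the analytic perimeter on disc and ellipse fixtures. Perimeters of
ring-shaped vessels include the lumen boundary. Published per-object
perimeter tables depend strongly on the estimator chosen, so perimeter
comparisons across tools should be treated as approximate.

## Fixed post-processing

The pipeline is deliberately rigid — ROI restriction, then minimum-area
filtering, then NMS — because its purpose is standardization: every
evaluation sees the same procedure, and an audit trail records retained and
removed counts per step.

* **ROI restriction** uses the convex hull of the annotation points as a
  proxy for the capsule-bounded nodal region (annotation software often
  cannot export the true ROI polygon). Membership is by object centroid,
  boundary inclusive. A degenerate hull (fewer than 3 points, or collinear
  points) is an error, not an empty ROI: silently dropping every object
  would corrupt counts downstream.
* **Minimum-area filter** removes objects *strictly smaller than*
  `min_area_um2` (default 6 µm²). The default sits where a 2–8 µm² sweep
  on speck-contaminated synthetic fields minimizes count MAE without
  losing F1; the selection helper (`select_min_area`) reproduces that
  choice, breaking MAE ties by higher F1 and then by the smaller threshold.
* **NMS** visits objects in order of decreasing area (ties broken by
  ascending id) and suppresses any object whose centroid lies within
  `factor × min(r₁, r₂)` (default 0.7) of an already-retained object. A
  single greedy pass is provably a fixed point — no two retained objects
  can conflict — so the operation is idempotent. The default `suppress`
  mode keeps the larger object's geometry untouched. An optional `union`
  mode additionally folds each suppressed object into its suppressor
  (summed area, area-weighted centroid). The union is computed at the
  record level: at this stage of the pipeline objects are morphometric
  records, not pixel masks, so a pixel-accurate union is out of reach by
  design; the record-level merge is the conservative approximation and is
  off by default.

## Matching

Matching is one-to-one by construction (each predicted and each reference
vessel appears in at most one pair), computed with the Hungarian algorithm
(`scipy.optimize.linear_sum_assignment`). The gates define admissibility;
the assignment then maximizes the number of admissible pairs and, among
maximum-cardinality assignments, minimizes total centroid distance. This
two-level objective is implemented with a sentinel cost (1 + the sum of all
admissible costs) on forbidden cells, which strictly dominates any feasible
total; sentinel pairs are discarded afterwards. Distance is the natural
cost because it is the only pairwise dissimilarity the gating criteria
define. Ties between distinct optimal assignments are resolved
deterministically (lexicographic pair order on the solver output).

Both gate inequalities are strict, so boundary cases
(|A_p − A_g|/A_g exactly 0.30, or d exactly min(r)) are *not* admissible.
The relative-area denominator is the reference area. The centroid-gate
multiplier α defaults to 1.0, the value implied by the matching inequality
d < min(r_p, r_g); the sensitivity sweep covers 0.1–1.0, so stricter
operating points (for example α = 0.5) are first-class rather than a
separate mode. The `circle_iou` mode is a self-contained alternative gate:
a pair is admissible when the IoU of the two equivalent circles reaches the
threshold (default 0.50, the usual Dice/Jaccard-style criterion), with no
additional area gate; whether the threshold itself passes is configurable
(`ge`, the default, or `gt`). The two-disc IoU uses the exact closed-form
lens intersection with an explicit containment branch — no numerical
integration, hence bit-reproducible.

## Metrics and agreement statistics

Ratios with zero denominators are reported as *undefined* (`None` /
exceptions), never coerced to 0 or 1. In sparse, low-prevalence regions
(a few dozen vessels) this distinction is material: an ROI with no
predictions has undefined precision, and conflating that with 0 would
poison pooled summaries. Per-ROI and pooled (summed-count) detection
metrics are both reported and labelled, because averaging rates and pooling
counts answer different questions.

* Wilson score intervals (via `statsmodels`) accompany precision and
  recall; they behave correctly at 0/n and n/n.
* **ICC(3,1)** is the two-way mixed, single-measure, *consistency*
  intraclass correlation (Shrout–Fleiss), computed directly from the
  two-way ANOVA mean squares with k = 2 raters:
  (BMS − EMS) / (BMS + (k−1)·EMS). It is invariant to a constant offset in
  either rater and to common rescaling; tests cross-check it against an
  independently written ANOVA oracle and against `pingouin`.
* **Bland–Altman** limits use the n−1 sample SD and the literal 1.96
  multiplier (not a t-quantile), so the limits are symmetric about the mean
  difference and the interval width is exactly 3.92·SD. Consequently any
  two of (mean, lower, upper) determine the third — a useful internal
  consistency check on published tables.
* **Proportional bias** is ordinary least squares of the difference
  (Pred − GT) on the mean count and on ROI area. Single-covariate fits and
  the joint two-covariate fit are all exposed: with very few ROIs
  (e.g. three) the joint fit with an intercept has zero residual degrees of
  freedom, and its p-values are reported as undefined rather than invented.

* The **Friedman statistic** is implemented directly in its tie-corrected
  rank chi-square form (average ranks within blocks; p from χ²(k−1))
  because the scipy implementation refuses the two-treatment case, which
  block designs with paired conditions need. It is numerically identical
  to scipy for k ≥ 3, with and without ties; a table whose blocks are all
  internally tied carries no ordering information and returns (0, 1).
  Wilcoxon signed-rank tests (zero differences dropped, exact null for
  n ≤ 25 without ties, normal approximation above) are always reported
  with both raw and Bonferroni-adjusted p-values rather than adjusting
  conditionally.

## Synthetic vessel fields

The generator emulates the morphometry of CD34-stained nodal regions:
log-normal vessel areas (default median 100 µm², log-SD 0.8, floor 8 µm²)
with a separately injected large-vessel tail (default 0.5% of instances at
3,000–8,000 µm²), and a 0.3/0.4/0.3 mixture of filled discs, annuli
(vessels with unstained lumina) and dilated curved polylines (longitudinal
cuts). Real nodal ROIs carry counts from a few hundred to >10,000 at
densities near 1.3×10⁻⁴ vessels/µm²; rasterizing such regions at
0.137 µm/px would need multi-gigapixel arrays, so the desk-scale default is
a 500×500 µm tile at 0.5 µm/px with 150 instances (the dropout scenario
uses 900×900 µm with 500). The physical area distribution is preserved;
only the sampling grid is coarser. Placement is rejection sampling,
largest-first, under two hard constraints: a one-pixel clearance between
instances (so connected-component labelling of the binarized field cannot
merge neighbours) and a centroid separation exceeding min(r₁, r₂) of every
pair (so no two *true* vessels ever fall inside each other's NMS gate at
any supported factor). If the requested density cannot be met the shortfall
is reported, never silently absorbed.

The degradation model reproduces the error modes seen in practice:
per-instance dropout; false-positive specks (default 2–5.5 µm², i.e.
strictly below the 6-µm² filter, placed inside the hull of the truth
centroids so they exercise the area filter rather than the ROI step);
fragmentation of large vessels into nearest-seed pieces with eroded
borders; centroid jitter; and multiplicative area noise realised by
peeling/annexing pixels by distance transform, exact in pixel count. Every
event is written to a ledger mapping each predicted object to its origin
(true detection, speck, fragment), so expected TP/FP/FN after the pipeline
are known exactly and tests can assert equalities, not just tendencies.

All randomness flows from one `numpy.random.Generator` seeded explicitly;
identical seeds give bit-identical rasters.

**What passing synthetic tests does not show.** The generator does not
simulate staining appearance, segmentation-model behaviour, annotator
variability, or the spatial correlation of errors with tissue structures
(capsule damage, germinal centres). Results on synthetic fields validate
the *measurement machinery* — post-processing, matching, metrics,
statistics — not the accuracy of any particular segmentation model on real
slides.

## Problem sizes and numerical checks

The shipped test and acceptance workloads use: 500 random ≤6×6 assignment
problems against exhaustive enumeration; 12-point randomized (r₁, r₂, d)
grids with 10⁷-point Monte-Carlo sampling per point (closed-form two-disc
IoU agrees within 10⁻³); a 500-instance field with 20% dropout for
binomial recall recovery; and 2,000 simulated 60-block × 3-treatment
tables for Friedman type-I calibration (rejection rate at 0.05 within
3 Monte-Carlo SE). Limits-of-agreement identities are asserted to 10⁻⁹.
These sizes keep a full run in tens of seconds while leaving the
statistical checks well-powered.

## Known limitations

* Matching scores elongated vessels approximately: equivalent circles
  under-represent high-aspect objects, mitigated but not removed by the
  combined centroid + relative-area gate.
* Fragment aggregation credit (many-to-one matching) is out of scope; a
  fragmented large vessel contributes at most one TP and the remaining
  fragments count as FPs until NMS removes them.
* The record-level `union` NMS mode approximates the pixel union (see
  above).
* Whole-slide pyramid formats are not read; analyses operate on cropped
  single-region rasters (TIFF/PNG).
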