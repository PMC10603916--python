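# Methods

`postura` implements a marker-based photographic posture assessment: a
subject photographed in four views (anterior, posterior, left/right
lateral) wearing 29 green spherical markers on 17 anatomical sites
(12 bilateral), with a 20 cm blue rectangle and a red plumb string in
the scene.  The pipeline detects the markers as color blobs, calibrates
a metric, gravity-aligned frame from the two references, computes 38
anatomical angle/distance features, compares two measurement sources
statistically, and screens for posture-problem evidence with LDA/kNN
classifiers.  Because real study photographs of this kind are not
distributable, a synthetic-scene generator with exact ground truth is a
first-class part of the package and underlies the entire test suite.

## Synthetic scenes

`scene.render_view` rasters one view: anti-aliased colored disks at the
template's landmark positions, a filled vertical rectangle (left), a
thin near-vertical segment (right), additive Gaussian pixel noise, all
on a configurable background.  Anti-aliasing uses analytic coverage
(`alpha = clip(r + 0.5 − d, 0, 1)` per pixel for disks), and the ground
truth records the *continuous* disk centers, not rasterized centroids;
detection tests allow a ≤ 0.5 px gap for this.  Defaults are the
acquisition setup the package models: 20 mm marker diameter, 20 cm
rectangle length, green/blue/red object colors, 166.4 cm subject height
(the mean of the adult population the original screening study
measured), subject occupying 82 % of a 1280×960 px frame — which puts a
marker at ≈ 13 px diameter, comfortably above the 3 px floor below which
`render_view` refuses to raster a spec.  The same seed renders
bit-identical images.

The body frame is isotropic (both axes in units of one subject height),
so the deformation model's rotations are true rotations.  Posture
deviations are affine displacements of exactly the landmark groups they
involve: pelvic obliquity rotates the ASIS pair (anterior) and PSIS pair
(posterior) about the pelvis midpoint; shoulder drop rotates the
acromion pair; kyphosis/lordosis gains displace the respective spinal
apex sagittally in the lateral views (0.05 body heights per unit gain);
a scoliosis offset shifts the kyphosis apex laterally in the posterior
view.

`population.make_feature_population` samples per-subject deformations
from class-conditional normals and computes features geometrically
(without rastering), then adds independent N(0, 0.5) measurement noise
(degrees or cm) to every feature.  The default composition is the
screening-study population this package emulates — 16 none / 25 mild /
16 moderate-to-severe — with effects ordered by severity: mild ≈ 3° ±
0.7 pelvic obliquity and −2.5° ± 0.7 shoulder drop; moderate/severe ≈
8° ± 1.2 and −6° ± 1.2 plus a unit kyphosis gain and a 0.04 scoliosis
offset.  No quantitative clinical definition separates "mild" from
"moderate-to-severe" posture deviation; these effect sizes are package
conventions chosen to be ordered and physiologically small, not
clinical claims.  Subject height is fixed by default (`height_sd_cm=0`)
so that zero effects and zero noise reproduce identical rows within a
class; pass a height spread to add anthropometric variation.

What the generator does *not* emulate: photographic texture, clothing
and skin confusers (the false-marker problem of orange/red markers on
skin), shadows, partial marker coverage, perspective/parallax.  Passing
tests therefore demonstrate the correctness of the geometry, statistics
and bookkeeping — not robustness to real-world segmentation noise.

## Detection

Pixels are thresholded in HSV.  Hue is on the 0–360° circle; defaults
are green H ∈ [80°, 160°], blue H ∈ [200°, 260°], red H ∈ [0°, 20°] ∪
[340°, 360°] (two intervals for the wraparound), with S, V ≥ 0.3.
Components are 8-connected (prevents anti-aliased disks from splitting);
border-touching components are kept.

Shape descriptors per component:

* outer contour: subpixel marching squares at level 0.5 on the padded
  mask, simplified with a 1 px Douglas–Peucker tolerance.  The
  simplification matters: the raw staircase contour overestimates a
  digitized circle's perimeter by ≈ 6 %, which would push its
  circularity down to ≈ 0.89; after simplification a r = 50 px circle
  measures ≥ 0.95 and an ideal square exactly π/4.
* area = shoelace area of that contour; perimeter = its polygon length.
* circularity = 4π·area / perimeter², clamped to [0, 1] (a digitized
  circle can exceed 1 by a rasterization hair).
* convexity = area / convex-hull area (hull of the contour).
* inertia ratio = √(λ_min/λ_max) of the pixel-set second central
  moments: 1 for a circle, → 0 for a line; a 1-px-wide component gives
  exactly 0 without error.

Marker blobs must pass all four filters; defaults (area 80–8000 px²,
circularity ≥ 0.6, convexity ≥ 0.85, inertia ≥ 0.4) accept a rendered
20 mm marker at the default scene scale and reject both references.
The scale rectangle is the largest blue component with circularity
≤ 0.85 and area ≥ 300 px²; its pixel length is the longer side of the
minimum-area rotated bounding rectangle of its contour; a second
candidate within 90 % of the winner's area is an ambiguity error.  The
plumb line is the most elongated red component with inertia ratio
≤ 0.2; its direction is the principal axis of the pixel set, oriented
downward in image coordinates.  On a red background the string merges
with the wall into one compact blob and the detector raises a distinct
"plumb line not found" error — the one background/color combination the
physical setup cannot survive.

## Calibration

Conventions, fixed once: image origin top-left, x right, y down, pixel
centers at integer coordinates; world frame in cm, y up, rotated so the
plumb direction is exactly vertical.  `cm_per_px` = known rectangle
length / measured pixel length; `rotation_deg` ∈ (−45°, 45°] is the
plumb's signed deviation from the image vertical.  Angles between
points are invariant under this transform; alignment angles (measured
against the horizontal) change by exactly the plumb rotation, which is
the point of carrying the plumb.  No parallax or perspective correction
is attempted; one global scale per image, each photo calibrated by its
own rectangle.

## Landmark labeling

Blobs carry no identity.  Labeling matches the blob cloud to the view's
template: both clouds are normalized robustly (coordinate-wise median
center, median pairwise distance scale — immune to a few far-outlier
false detections), matched by exact optimal assignment on squared
distances, then a per-axis linear map into the template's unit bounding
box is fitted on the most trusted pairs (trimmed least squares) and the
assignment re-solved in that space.  There the rejection threshold
(default 0.01 in squared bounding-box units, i.e. 10 % of the body box
per marker) applies both per pair and on the mean; the assignment
matrix is augmented with opt-out columns at the threshold so an
implausible blob goes unassigned rather than displacing a good match.
Unmatched sites are flagged missing, unmatched blobs reported as
surplus; fewer than half the sites matched is an
implausible-configuration error.  The 0.01 default is > 4× any residual
the renderer/detector produces yet tight enough that an affine fit to
arbitrary scatter cannot pass — a looser 0.04 was found to admit
chance-level fits of uniform random points.  In the anterior view the
image is mirrored (image-left is the subject's right); posterior and
lateral views are not.  Manual overrides can fill occluded sites or
replace detected ones; provenance (detected/manual/missing) is kept per
landmark.

## Features

All 38 features derive from four primitives on calibrated world
coordinates (+x toward the subject's anatomical right):

* signed alignment angle against the horizontal, in (−90°, 90°],
  positive when the subject's right end is higher (AHA_A, ASISHA,
  AHA_P, PSISHA);
* unsigned three-point vertex angle in [0°, 180°] — a collinear spine
  reads 180°, deliberately the raw angle rather than its supplement
  (TKA, LLA, PKLA, ALA, TKC, LLC, KA);
* angle between two undirected lines, acute convention [0°, 90°] by
  default so bilateral instances are comparable, with an obtuse option
  (ASA, ASISLA, AKLA, AVA, PSISLA, PLA, LFA);
* Euclidean distance in cm (AJND, AAD, ALLL, APD, PLLL).

The knee angle seen from behind (PKLA) is computed as the vertex angle
at the popliteal fossa between the thigh line (to the trochanter) and
the shank line (to the posterior intermalleolar point); the grouping of
its three landmarks into lines is ambiguous in the source description
and this reading is flagged for review in the code.  The thoracic and
lumbar curvature features use the same vertex formula in the posterior
(TKA/LLA) and lateral (TKC/LLC) views on their respective landmark
positions.  Features whose landmarks or view are absent are NaN, never
imputed.

## Agreement validation

For two same-subject feature tables (e.g. this software vs a clinical
reference), per feature: Shapiro–Wilk on each source's sample (the gate
applies to the sources, not the differences; a config switch flips
that); both normal at the gate α (default 0.05) → paired t on the
differences, else Wilcoxon signed-rank (zeros discarded, exact null for
≤ 25 nonzero differences, normal approximation with continuity
correction above).  All decisions are reported at both α = 0.05 and
α = 0.1.  A feature significant at *both* levels triggers Tukey
1.5×IQR outlier removal on the differences (both sources lose the same
subjects, minimum 5 pairs) and a repeat analysis.  Equivalence is a
paired TOST on the t distribution with n−1 df along the widening ladder
±0.01 → ±0.05 → ±0.06 (native feature units; a config option
standardizes by the sd of the differences), stopping at the first rung
equivalent at α = 0.05.  TOST p is provably non-increasing in bound
width, asserted empirically as well.  Zero-variance differences are
handled exactly: equivalent iff the constant difference lies strictly
inside the bounds.  The whole report is a pure function of the two
tables and the config.

## Classification

Three filter rankings order the features: information gain after
equal-frequency 4-bin discretization; the χ² statistic of the binned
feature × class table (constant features are excluded with a warning);
ReliefF (k = 5 hits/misses, every instance, min–max scaled features,
miss terms weighted by class priors).  Ties break by feature name.  The
three fixed feature sets the original screening configuration used ship
as named presets (`multiclass`, `level1`, `level2`); the automatic mode
takes the union of each method's top-m and records which method chose
what.  Ranking on the whole labeled dataset before evaluation leaks
label information into feature selection; the presets sidestep this,
and the automatic mode is documented as leakage-prone when applied to
the full table.

Models: LDA (sklearn) and a deterministic kNN — Euclidean on features
z-scored with training-set statistics, vote ties broken by smaller mean
neighbor distance, then smaller class index.  Schemes: stratified
10-fold CV (metrics pooled over the union of out-of-fold predictions)
and a stratified 70/30 split, both seeded.  Stratification protects the
16-subject classes; with 57 subjects a fold holds only ~6.  k is chosen
by evaluating a grid (default 1–21) under the scheme and keeping the
five lowest-error values, ties toward smaller k.  Metrics: accuracy and
one-vs-rest F1 per class (percent), always recomputable from the stored
confusion matrix; zero-division F1 is 0 with a flag.

The two-level binary cascade trains level 1 on evidence-vs-none over
all subjects and level 2 on mild-vs-moderate/severe over the true
with-evidence subjects (41 of 57 under the default composition).  The
combined three-class report chains level-1 "evidence" predictions
through level 2, using out-of-fold level-2 predictions where the
subject was in the level-2 evaluation and a level-2 model trained on
all with-evidence subjects otherwise.  Level-2 10-fold CV on fewer than
20 subjects is refused as a scheme degradation.

## Problem sizes and numerical choices

The verification suite uses 200 rendered scenes (plus 40 with one
occluded site) for the detection round-trip, 200 random convex polygons
for the descriptor oracle, 300 random configurations for the geometry
oracle, 2000/1000 Monte-Carlo replicates at n = 57 for the
Shapiro–Wilk and gated-test type-I rates, 200 datasets for TOST ladder
monotonicity, 1000 replicates for the boundary-declaration rate, and
500 permutation replicates for the chance-level check — sizes at which
the binomial error of every rate sits well inside its asserted band.
Descriptor/geometry oracles are independent re-derivations (explicit
shoelace loops, monotone-chain hull, closed-form 2×2
eigendecomposition, arctangent identities) and agree with the
implementation to ≤ 1e-6 / 1e-9.  Degenerate inputs are errors, not
silent values: coincident points for angles, constant samples for
Shapiro–Wilk, all-zero differences for the paired tests, markers that
would raster under 3 px.

## Known limitations

* Blob detection assumes near-uniform marker color patches; no exposure or
  white-balance normalization, no multi-color markers.
* The labeling template must roughly match the subject's proportions;
  extreme postures outside the deformation model could exceed the
  rejection threshold and be reported missing rather than labeled.
* Synthetic severity classes are strongly separated by construction;
  classifier accuracies on them say nothing about clinical accuracy.
* Equivalence bounds in native units mix degrees and cm across
  features; the standardized option exists but changes interpretation.
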