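# Methods

This note documents the models, conventions and numerical choices
behind `crabgrade`, and states what the synthetic validation does and
does not demonstrate.

## Coordinate and rasterisation conventions

All modules share one convention: x grows rightward, y downward, origin
at the top-left *corner* of the image; pixel `(row i, col j)` has its
center at `(j + 0.5, i + 0.5)`. A polygon rasterises to the set of
pixels whose center lies inside the closed ring, with centers exactly
on an edge included (tie toward inclusion). This makes rasterisation
deterministic and checkable against an exhaustive point-in-polygon
scan, which the test suite does on small images.

Every downstream quantity — pixel counts, extents, calibration —
inherits this convention, so it is load-bearing: a half-pixel shift in
the convention changes the measured extents by one pixel.

## Calibration

The scene contains a solid, axis-aligned reference square of known
physical side `c` (default 2 cm). Its pixel side is estimated as
`sqrt(N)` from its pixel count `N` rather than from bounding-box edges,
which averages out boundary raggedness. The scales are then
`L_a = L_b = c / sqrt(N)` (cm/px) and `S₀ = L_a·L_b` (cm²/px), with the
consistency `S₀ = L_a·L_b` enforced to 1e-6 relative as a type
invariant. A marker bounding box with aspect ratio outside [0.8, 1.25]
triggers a skew warning (the square should project to a square when the
camera is normal to the platform).

## Tilt correction

Measurements are axis-aligned extents, so the carapace must first be
rotated to a canonical orientation: its longest line horizontal. The
orientation estimate is the second-central-moment (equivalent-ellipse
major-axis) angle, `0.5·atan2(2μ₁₁, μ₂₀ − μ₀₂)`, of the set-pixel
centers. An enclosing-rectangle orientation was considered and
rejected: for a rasterised near-circular carapace the minimum-area
rectangle's orientation is genuinely unstable (a 30°-rotated ellipse
with axis ratio 1.2 yields a 45° rectangle on the quantised hull),
while the moment estimate stays within ±0.3° across the working range.
The mask is rotated by the negative of that angle about its
bounding-box center with nearest-neighbor resampling — masks stay
binary, and the pixel count is taken *after* rotation, so area and
extents come from the same raster. The applied angle is reported in
(−90°, 90°].

For a perfectly circular mask the orientation is undefined; any angle
is acceptable there because the measured extents are rotation-invariant
to within the resampling error (≤ 2 %, verified in tests).

## Morphometrics

With a tilt-corrected mask and a calibration: `N₀` is the set-pixel
count, `L₂` the horizontal inclusive extent (`X_max − X_min + 1`) and
`L₁` the vertical inclusive extent. Then

- projected area `A = S₀·N₀` (exact by construction),
- length `L_l = L₁·L_a`, width `L_w = L₂·L_b`.

Axis assignment: after alignment the *horizontal (long) extent is the
carapace width* (medial-lateral) and the vertical extent the length
(anterior-posterior), because mitten crab carapaces are wider than
long. Extents are inclusive so a one-pixel line has extent 1, not 0.
The reference origin `(O_x, O_y)` is the bounding-box center,
`((X_max + X_min)/2, (Y_max + Y_min)/2)`.

Carapace thickness `H` is always an input from the specimen metadata;
a single dorsal view cannot measure it.

## Condition factor and grading

Fatness is the improved Fulton-type condition factor `K = 3W/(A·H)`
(W in g, A in cm², H in cm): weight normalised by a volume proxy suited
to a flat-bodied crustacean. The national grading standard expresses
fatness on a percent scale whose algebraic relation to `K` is not fixed
by the definition above; the package uses a single linear mapping
`fatness% = 20·K` (configurable constant `PERCENT_PER_K`). The factor
20 was chosen once so that percent-fatness values typical of market
crabs (43–76 %) back-compute, at plausible areas (28–60 cm²) and
thicknesses (~2.4–3.4 cm), to live weights inside the observed
85–250 g range — i.e. the mapping is self-consistent with the
published morphometry. Externally supplied percent-fatness values can
be graded directly, bypassing the mapping.

Grade bands (percent scale), checked top-down:

| sex | I | II | III | IV |
|---|---|---|---|---|
| male | > 65 | (62, 65] | (58, 62] | ≤ 58 |
| female | > 58 | (55, 58] | [51, 55] | < 51 |

Band edges follow a half-open "a higher grade wins only strictly above
its threshold" convention so the bands partition all of K ≥ 0; the
printed female III band (51–54) abuts II at 55 with a gap, which is
closed by extending III up to 55 (conservative: the gap grades lower).
The female lower edge 51 is inclusive to III because IV is defined
strictly below 51. No specimen in the published validation panel sits
on an edge, so these conventions are not constrained by data; they are
shipped as an overridable YAML table.

## Sex and integrity decisions

The abdominal flap of a male is a pointed triangle, of a female a
broad semicircle. The discriminant is *rectangularity*: flap pixel
area divided by the area of its minimum-area rotated enclosing
rectangle. Any triangle fills exactly half of its tightest rectangle
(ratio 0.5); a semicircle — and a full circle — fills π/4 ≈ 0.785. The
frozen cutoff 0.64 sits between the two regimes; the returned score
grows with distance from the cutoff and saturates at the ideal-shape
values. This statistic is invariant to rotation, scale and moderate
boundary noise, which is why it was preferred over solidity (both flap
shapes are convex, so solidity does not separate them) or local tip
curvature (noisy on rasterised boundaries).

Integrity is a count: intact iff at least `expected_limb_count`
(default 10 = 8 legs + 2 chelipeds) limb components are present.
Regenerated or partially fractured limbs that appear visually intact
are out of reach of this rule, as they are for any silhouette-based
method.

## Baseline segmenter and backend contract

The pipeline accepts any backend `image -> [labeled instance masks]`.
The shipped baseline thresholds the Euclidean RGB distance to the known
platform color (default orange (230, 140, 40), threshold 40 on the
0–255 scale) and takes 8-connected components of at least
`min_region_px` (default 50) pixels, largest first, confidence 1.0.
The largest component is the carapace (dorsal-scene assumption); of the
remainder, components with near-unit bounding-box aspect (0.8–1.25)
*and* near-full bbox coverage (extent ≥ 0.85) are the calibration
marker — the marker is an axis-aligned solid square, so it satisfies
both, while limbs at any orientation fail at least one — and everything
else is a limb. The baseline is fully deterministic.

## Joint augmentation

Geometric augmentation ops (rotate, flip, scale, translate, shear)
compose into one exact affine map applied identically to the image
raster and to the polygon coordinates, so annotations never drift from
pixels; Gaussian noise perturbs the image only and is seeded. Polygons
leaving the canvas are clipped against the image rectangle (true
polygon clipping, not coordinate clamping, so rings stay simple).

## Evaluation metrics

Detections are matched to ground truth greedily per class in
descending confidence at mask-IoU ≥ 0.5 (the conventional threshold);
each truth absorbs at most one detection. AP uses 101-point
interpolation — the monotone precision envelope sampled at recalls
0.00…1.00 — the convention of the detector family this package is
meant to sit behind; mAP is the unweighted class mean. The test suite
checks AP against an independent brute-force interpolation oracle.
"Average accuracy" of a confusion matrix is the *macro* average of
per-class row accuracies, not the pooled accuracy; the two differ under
class imbalance (e.g. per-class 92.86 %/93.33 % gives macro 93.10 % but
pooled 93.04 %), and macro is what per-class test reporting implies.

## The phantom generator

A phantom is an elliptical carapace (semi-axes `a ≥ b` cm, so truth
width = 2a, length = 2b, area = πab) at a known rotation, with up to
ten capsule-shaped appendages and an axis-aligned 2 cm calibration
square, on the uniform orange platform, imaged at 25 px/cm into a
480×480 frame with Gaussian pixel noise (σ = 2 by default). The
ventral view holds the sex-dimorphic flap. Weight is back-computed
from a target percent fatness through the `20·K` mapping, so the
end-to-end grade is known exactly. Cohorts are stratified by sex and
target grade; per-grade fatness targets are drawn uniformly inside the
band with a 0.5-point inset from the edges, so each cohort member
represents its grade distinctly; 80 % of phantoms are intact, the rest
lose 1–3 limbs. Morphology ranges (half-width 2.5–3.6 cm, thickness
2.4–3.4 cm, length/width ratio 0.75–0.95) match market-sized mitten
crabs. All randomness derives from the seed; identical specs give
bit-identical output.

Deliberate simplifications, and hence the limits of what passing tests
show: appendages are drawn *detached* from the carapace (a 3 px gap) so
connected components separate them — real crabs need an instance
segmenter for this; the scene has no occlusion, shadows, water stains,
rope bindings or specular highlights; flap shapes are ideal triangles
and semicircles. The phantom cohort therefore validates the
*measurement and decision machinery* (calibration, tilt correction,
pixel-count morphometrics, the condition factor, band assignment, the
metric implementations) — it says nothing about the segmentation
accuracy achievable on real photographs, which in a deployed system
resides in the trained backend.

## Problem sizes and tolerances

The acceptance run uses a 200-phantom cohort (sex-balanced, all four
grades), a rotation sweep at 0°–75° in 15° steps, and the 20-row
published validation panel; at these sizes the whole run completes in
well under a minute on one CPU. Observed recovery on the cohort: area
MAPE ≈ 0.08 %, length ≈ 0.6 %, width ≈ 0.5 %, sex/integrity/grade
agreement 100 %, detection mAP 1.0, rotation spread ≤ 1.7 % — against
test thresholds of 2 % MAPE, 100 % sex, 95 % integrity/grade, 2 %
spread. Degenerate inputs (empty masks, zero-area polygons,
non-positive weights, unknown labels, zero metric denominators) raise
typed validation errors or warnings as documented per function.
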