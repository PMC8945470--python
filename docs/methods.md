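# Methods

This note documents the models and procedures implemented in
`plantarsites`, the tunable parameters and their defaults, what the
synthetic scene generator does and does not emulate, and the design
choices made where the problem left the design genuinely open.

## Problem setting

A plantar acquisition scene is a 24-bit RGB photograph of both bare feet
against a dark matte board, taken roughly perpendicular to the soles
from about a metre away under uncontrolled room lighting. Two brightly
colored square targets of known physical size sit near the top corners
of the board; they relate pixel distances to millimetres and double as a
crude color reference. The task is to output, per foot, the nine
monofilament testing sites in scene pixel coordinates: 1 hallux,
2 third toe, 3 fifth toe, 4/5/6 first/third/fifth metatarsal heads,
7 medial midfoot, 8 lateral midfoot, 9 heel. This site-id ↔ anatomy
mapping is a package convention and is configurable.

Coordinates everywhere are 0-based, origin top-left, `x` = column,
`y` = row. Angles are in degrees, positive when a foot leans clockwise
on screen, range (−90°, 90°].

## Background segmentation

The V plane of HSV (per-pixel max of R, G, B) is histogrammed into 256
bins; its mode is the dark background. The binarization threshold is

    t = clip(round(factor · mode), t_min, 255)

with `threshold.factor = 2.5` and `threshold.t_min = 20`. The floor
matters: an ideal black background has mode 0 and would otherwise select
the whole frame. Ties in the histogram break toward the lowest
intensity. The threshold is applied to the ITU-R 601 luma of the image
(the grayscale to threshold is not uniquely determined by the V-based
rule; luma is the documented, configurable choice here).

The binary image is cleaned by a morphological opening with a disc whose
radius (`morphology.open_radius_px = 5`, specified at a 5328-px-wide
reference resolution) scales linearly with image width and never drops
below 1 px. Connected components overlapping detected marker boxes are
removed, components smaller than `feet.min_area_fraction = 0.01` of the
scene are ignored (this rejects background reflections), and the two
largest survivors are the feet. Fewer than two is a run-level failure
(`FeetNotFound`) that must reach a human, matching how a screening
workflow treats an unusable image. Side labels come from horizontal
order; with a supine patient and the camera facing the soles, the
image-left region is the patient's right foot
(`feet.image_left_is = "right"`, configurable).

Foot contours, when requested, are the Moore-traced outer boundary of
the closed mask, smoothed with a cyclic moving average (window 5) —
an ordered pixel chain usable for edge-accuracy scoring.

Markers are detected by hue/saturation/value bounds (yellow hue 38–72°,
pink 300–355°, saturation ≥ 0.45–0.5, value ≥ 120). Hue and saturation
are invariant to the multiplicative brightness variation that
uncontrolled lighting produces, which plain RGB bounds are not; skin
(hue ≈ 21°, saturation ≈ 0.34) falls outside both ranges. The largest
component per color with a roughly square bounding box (aspect within
[0.7, 1.43]) is accepted; mm-per-pixel is the mean of
`size_mm / mean(bbox edges)` over accepted markers
(`markers.size_mm = 76` — a standard sticky-note width; the true marker
size is whatever the acquisition used and must be configured). No marker
is a state, not an error: the scale falls back to config or is reported
absent, in which case the scoring radii operate in pixels.

## Foot normalization

Each foot region is cropped with a margin of
`normalize.margin_fraction = 0.05` of the larger bounding-box edge,
padded to a square canvas large enough that no rotation clips it, and
rotated upright. The tilt estimator is the chord from the topmost
foreground pixels (centroid column of the top row) to the bottommost.
On a rounded, asymmetric silhouette this estimator is biased — the
tangent points of the hallux cap and heel ball move along their arcs as
the foot tilts, so a single estimate underestimates large tilts by
roughly a quarter. Normalization therefore iterates estimate-and-rotate
(`normalize.refine_iterations = 3`); the iteration converges to the pose
in which the chord is vertical, which this package defines as the
canonical upright pose. Rotations use bilinear interpolation for the
image, nearest-neighbor for the mask, and fill exposed corners with
black so the dark-background assumption survives downstream.

Every crop/pad/rotate step is recorded in a `TransformChain`;
`remap_point` applies the inverse steps in reverse order and rounds to
integer pixels (round half away from zero, as all coordinate rounding in
this package), erroring if the result leaves the scene raster.

The toes sub-view is the top `normalize.toes_fraction = 0.25` of the
foot's mask rows; the plantar view is the remainder. The split row is
not critical: the contour and track signals live well inside the top
quarter and the guideline construction uses the full mask.

## Toe sites (1–3)

The contour function `y_top(x)` is the per-column topmost foreground
row. Toe tips are its local minima. Peak detection smooths the profile
(5-column moving average), removes the linear trend across the foot
(a residual tilt slopes the profile and deflates scipy's prominence for
downhill toes), and keeps minima with prominence at least
`toes.peak_prominence = 0.02` of the foot length L — raw
first-derivative sign inversions alone would fire on raster noise.
Detected peaks are then relocated to the local minimum of the
*untrended* profile, and the chosen hallux peak is refined to the
centroid of the near-apex plateau (columns within 1.5 px of the local
minimum over a ±8 %-of-width window), because a toe cap is locally flat
and the raw argmin wobbles by several columns.

Site 1 is the first prominent peak scanned from the medial edge
(left→right for a left foot), which stays correct on the occasional
foot whose second toe out-prominences the hallux. The peak is expected
around `toes.hallux_band_center = 0.20` of the foot width from the
medial edge, ± `toes.band_tolerance = 0.10`; a peak outside that band
indicates a strongly angled phalanx and triggers a re-search restricted
to the band (falling back to the original peak if the band is empty).
The site sits `toes.hallux_depth = 0.10`·L below the contour.

The toe track samples grayscale intensity at
`(x, y_top(x) + 0.05·L)` (`toes.offset_fraction`). Columns are
classified bright/dark against the midpoint of the track's robust
min/max (5th/95th percentiles); a spread under `toes.min_contrast = 20`
intensity levels flags the classification low-confidence and suppresses
small-toe output. Bright spans are toes, dark spans inter-toe webbing.
The bright span nearest the medial edge whose width is within
`toes.hallux_span_tolerance = 0.15`·W of `toes.hallux_span = 0.40`·W is
the hallux span; narrow slivers medial of it are silhouette-margin
artifacts and are skipped. The remaining spans are assigned medially to
laterally as toes 2–5 **only if** all four are present with widths
within `toes.proportion_tolerance = 0.10`·W of
`toes.small_span = 0.15`·W — a merged or hidden toe breaks the
positional count (and a merged pair can itself pass the width test), so
any deviation from the complete five-span pattern abstains rather than
guesses. Site 2 comes from the third toe's span and site 3 from the
fifth's, at the contour peak column when one lies inside the span (the
span center otherwise), `toes.small_toe_depth = 0.05`·L below the
contour. The depth is a declared assumption: no placement rule for the
small-toe sites is uniquely determined by anatomy, and small toes are
proportionally shorter than the hallux, so half its 10 % rule is used.
Emitted small-toe sites always carry at least one of {color, contour}
evidence plus the proportion predicate; partial output is the designed
behavior, not a failure.

## Plantar sites (4–9)

On the normalized binary mask, rows at `plantar.upper_row_fraction =
0.40` and `plantar.lower_row_fraction = 0.80` of the mask's vertical
extent are scanned for their outermost foreground transitions, giving
left/right border points and midpoints. The axis passes through the two
midpoints; two inner guidelines pass through the upper row's w/4 and
3w/4 points parallel to the axis (the quarter split reflects the
hallux being proportionally wide and the fourth/fifth toes sitting
close together). Walking each line upward from the bottom image edge,
the first background→foreground transition is the heel start. A site is
placed on its line at a configured fraction of the extent from the heel
start to the topmost foreground row of the mask. The extent deliberately
uses the mask-global top rather than the per-line top: a near-vertical
axis line threads the gap between the second and third toes, where
"topmost foreground along the line" flips discontinuously with
single-pixel raster changes, while the global top row (the hallux tip)
is stable.

Default proportions (`plantar.proportions`, all configurable and to be
treated as tunable assumptions, not ground truth):

| site | line          | fraction |
|------|---------------|----------|
| 4    | medial inner  | 0.72     |
| 5    | center (axis) | 0.72     |
| 6    | lateral inner | 0.72     |
| 7    | medial inner  | 0.45     |
| 8    | lateral inner | 0.45     |
| 9    | center (axis) | 0.12     |

The metatarsal-head row sits at ~72 % of the heel-to-toe extent, the
midfoot pair at ~45 %, the heel site at ~12 %, from standard SWME site
anatomy. Medial/lateral line assignment mirrors between left and right
feet.

## Evaluation metrics

* `feet_detection_accuracy = n_correct / n_feet`.
* `mask_dissimilarity(A, B)` — population count of `A XOR B` over the
  pixel count; a resolution-invariant number in [0, 1]. Edge accuracy is
  the fraction of such distances at or under
  `evaluation.edge_margin = 0.05`.
* `site_location_accuracy` — fraction of reference sites whose estimate
  lies at Euclidean distance **strictly** less than r (5 mm for sites
  1–3, 10 mm for 4–9; pixel fallbacks of 10/20 px when no calibration
  exists). A reference without an estimate is a miss — this is the
  declared convention; with a pipeline that never guesses, misses are
  the only way a per-site accuracy drops below 1.
* `jaccard_index` — |A∩B| / |A∪B|, defined as 1 when both masks are
  empty (perfect agreement about absence; the ratio is 0/0 there).
* For region-overlap scoring of point estimates, each point is expanded
  to a disc of its admissible-error radius and the two discs are
  compared by Jaccard (`point_pair_jaccard`), computed on a local raster
  window.
* `summarize` aggregates per-site accuracies over strata (overall, per
  foot side, per sex when metadata is present) and five-number summaries
  of the per-site Jaccard distributions.

All metric implementations are tested for exact agreement with naive
double-loop oracles and for the metric laws (symmetry, identity,
triangle inequality, boundedness, containment monotonicity).

## Synthetic scene generator

Real annotated plantar photograph collections are clinical data and not
freely available, so testing runs on synthetic scenes with exact truth.

**Silhouette.** A foot of length `foot_length_mm = 246` (width ratio
0.40) is the union of: five vertical toe capsules on a descending arc
(hallux radius 0.16 W at the medial fifth of the width; small-toe radii
0.055–0.070 W; tips protruding 16 %, 12.5 %, 10.5 %, 7.5 % and 4.5 % of
L beyond the inter-toe webbing at 0.16 L), a tapered body whose
half-width profile runs from 0.50 W at the metatarsal ball to 0.33 W
above the heel with a medial arch dip scaled by `arch_concavity`, and an
elliptical heel cap reaching y = L. Geometry is fully analytic, so foot
masks and toe tips are exact at any rotation; `toe_overlap` closes the
inter-toe gaps progressively and `toe_tilt_degrees` shears the toe
columns.

**Canonical pose.** The canvas pose at `orientation_degrees = 0` is the
one in which the hallux-tip→heel-apex chord is vertical — precisely the
pose the normalization stage converges to — and the stated orientation
tilts the foot clockwise from there. This makes generated orientations
directly comparable with estimated ones.

**Site truth.** Sites 1–3 are defined in closed form from the toe tips
(10 % / 5 % of the upright foot length below the hallux / small-toe
tips). Sites 4–9 are defined by the same guideline construction the
pipeline documents, applied to the clean upright silhouette; the
end-to-end recovery tests therefore validate the imaging chain
(thresholding, segmentation, rotation, remapping) rather than the
proportion constants themselves, which is the intent — the proportions
are a convention, the imaging chain is the algorithm under test.
Rotation is applied jointly to raster and truth.

**Rendering.** Scenes default to 1332×1029 px at 0.76 mm/px (a quarter
of the acquisition resolution per axis; the algorithms are
scale-normalized and desk-scale tests gain nothing from more pixels).
Background gray 12; skin (205, 160, 135) shaded by a per-column
inter-toe valley factor (dropping to 0.35 between toe axes above
0.24 L, which produces the dark webbing the toe track relies on); a
linear lighting gradient with configurable direction and amplitude;
optional elliptical background reflections; optional Gaussian shadow
lobes multiplying the scene (the failure mode of uncontrolled lighting
is shadowing of the plantar surface — a purely multiplicative gradient
is neutralized by the adaptive threshold and the track's adaptive
midpoint, as the robustness tests confirm); Gaussian pixel noise; and
the two markers (yellow/pink, 76 mm) at the top corners. All randomness
derives from the scene seed; geometry is seed-free.

**Presets.** `benign` draws anatomy and lighting from the nominal
acquisition conditions (orientation ±35°, gradient amplitude
0.05–0.2, noise σ 2–4, no reflections or shadows); `tilt_sweep` spans
±40° at fixed anatomy; `lighting_sweep` increases a combined
gradient + toe-region shadow severity from 0 to 1; `toe_overlap_sweep`
closes the toe gaps; `marker_proximity` moves longer feet toward the
markers. Identical (preset, n, seed) triples produce byte-identical
fixtures.

**What the generator does not emulate** — and hence what green tests do
and do not show: skin texture, callus and lesions; perspective from a
foot inclined toward the camera; JPEG artifacts on the scene (the codec
tolerance is exercised on the annotation layer); partial occlusion;
inter-foot shadowing; non-Gaussian sensor noise. Passing the synthetic
suites demonstrates the pipeline's geometric and photometric logic is
correct under the modeled conditions; it does not predict clinical
accuracy on real photographs.

## Problem sizes and numerical choices

The recovery suite uses 50 benign scenes (100 feet), the orientation
sweep 9 scenes, the lighting sweep 12; these sizes give stable
fractions while keeping the full test run in a couple of minutes on one
CPU. The lighting-degradation check compares mean localization error
across severity-quartile bins, scoring a missing site at twice its
admissible radius and a failed run as all-missing: under severe
degradation the pipeline (by design) abstains on toe sites, and without
a miss penalty abstention would spuriously *lower* the error of the
worst conditions. Tie-breaks and degenerate inputs: histogram ties take
the lowest intensity; centroids round half away from zero; a mask under
3 px of vertical extent has no orientation; two empty masks have
Jaccard 1; an empty toe track yields no spans and no small-toe sites.

## Known limitations

* The proportion table for sites 4–9 is a calibrated convention; on real
  feet it should be fit to annotated data before the accuracy numbers
  mean anything clinically.
* The chord orientation estimator assumes the hallux tip is the topmost
  silhouette point after convergence; extreme valgus deformity could
  break this.
* Site 2/3 abstention is conservative by construction: feet with fewer
  than four cleanly separated small-toe spans never receive small-toe
  sites.
* Scoring treats sites independently; no joint plausibility constraint
  (e.g., site 4 medial of site 6) is enforced or evaluated.
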