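# Methods

## Counting model

The counter treats a plate image as an intensity surface on which
colonies are dark basins. It makes two simplifying assumptions: the
number of colonies is the only quantity of interest, and each colony is
darker than its local background with one darkest spot marking its
center. Under these assumptions enumeration does not require
segmentation (thresholding plus watershed separation is notoriously
fragile for low-contrast, confluent colonies); it requires only that,
after background removal and noise suppression, each colony contributes
exactly one prominent regional minimum.

### Pipeline stages and parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| rolling-ball background subtraction | `rolling_ball_radius_px` | 50 px | must exceed the radius of the largest object to preserve; 50 px ≈ 4 mm diameter at 40 µm/px, headroom over the ≤ 2 mm colonies of a 24 h incubation |
| automatic contrast expansion | `contrast_saturation_fraction` | 0.0035 per tail | percentile stretch to the full 8-bit range; a small saturation makes the bounds robust to isolated extreme pixels |
| | `contrast_min_range` | 32 gray levels | degenerate-range guard, see below |
| median filter | `median_radius_px` | 6 px | ≈ 0.25 mm: the smallest object a human counter would accept; anything smaller (noise, microcolonies) is eliminated by design |
| brightness lift | `brightness_lift` | 135 | saturating addition that pushes residual background artifacts to pure white, leaving grayscale structure only inside colonies |
| minima detection | `min_prominence` | 10 gray levels | noise tolerance of the counter on the post-contrast scale, see below |

All stages are deterministic, shape-preserving and operate on 8-bit
grayscale; re-running the pipeline on the same input is bit-identical.
Contrast statistics are computed over ROI pixels only (marks or writing
outside the countable area must not skew the stretch), while the pixel
operators themselves run on the full frame; boundary effects stay
within the rim inset. Whether contrast should be normalized per wedge
segment or once per plate is not determined by the procedure this
follows; per-ROI normalization was chosen, making each wedge's counts
independent of its neighbors' colony opacity.

**Rolling ball.** Implemented as its morphological definition: grayscale
closing with a *spherical* (non-flat) structuring element of the given
radius, computed exactly by a row decomposition of the ball into 1-D
semicircle profiles, with edge replication at borders. Widely used
implementations approximate the ball by a downsampled paraboloid; the
exact operator was preferred because it is deterministic, has no hidden
scale parameters, and is testable against a brute-force oracle. The
operator contract — structures wider than twice the radius removed, dark
objects smaller than the ball preserved — is what the pipeline relies
on, not bit-equivalence with any particular tool. One consequence of the
exact definition: the closing hugs the tops of the noise, so a
*featureless* region's residual after subtraction is not flat but
carries smooth ball-scale undulations of ~10–20 gray levels.

**Degenerate-range guard.** That consequence motivates
`contrast_min_range`: on a colony-free ROI the percentile range of the
background-subtracted image is far below any real colony depth (colonies
are ≥ 60 gray levels deep by construction of the backlit imaging), and
stretching a ~20-level residual to [0, 255] would amplify those
undulations into false minima that survive median filtering with
prominences up to ~60 — no prominence threshold can separate them from
real colonies afterwards. The contrast expansion is therefore skipped
when the stretch bounds are closer than 32 gray levels: such a region
is declared featureless and the subsequent lift whitens it completely
(count 0). The value 32 sits midway between the largest observed
blank-plate residual ranges (~25) and the smallest colony depth (60)
and is exposed as a parameter. This generalizes the obvious degenerate
case (a constant image must pass through unchanged).

**Minima detection.** A regional minimum's *prominence* is its depth
below the lowest saddle connecting it (8-connectivity) to a deeper
minimum; the deepest minimum in the mask is referenced against the
mask's maximum intensity. The detector sweeps pixels in ascending
intensity with a union-find structure: each regional minimum starts a
basin; when basins meet, the shallower dies at the saddle, fixing its
prominence — 0-dimensional persistence of the sublevel filtration. Flat
plateau minima yield one point at the plateau's centroid pixel (ties
broken by smallest row, then column). Pixels at 255 are lifted
background and never count. `min_prominence = 10` was calibrated on the
synthetic-recovery suite: after the pipeline, true colony centers carry
prominences ≳ 40 while residual intra-colony noise stays below ~3, so
the threshold has a wide margin in both directions; it remains the one
genuinely free parameter and should be re-calibrated (together with a
gold-standard comparison) when a new sample type is introduced.

**Rounding.** Every linear rescaling rounds half *up* (`floor(x+0.5)`),
once, at the end of the computation. This convention also reproduces the
benchmark table's printed count ratios (e.g. 1.125 → 1.13).

**Coordinates** are 0-based `(row, col)` at pixel centers.

## Plate geometry

`PlateLayout` fixes the dish center and radius in pixels (dish position
is assumed mechanically fixed by a jig, so ROIs are predefined rather
than detected). The countable disc is inset `rim_inset_mm` (default
3 mm — "a few millimeters" is the working practice; exact values are
lab-specific) to avoid rim colony clusters and the thicker broth layer
near the edge. Six-segment layouts split the inset disc into wedges of
60° minus `segment_gap_deg` (default 4°), mirroring the colony-free
border strips drawn on segmented dishes; the gap guarantees wedge
disjointness so no colony is counted twice. Segment counts are
multiplied by 6 for full-plate equivalence. Wedge membership is an
analytic test (radius and angle), rasterized once per image shape and
cached.

## Synthetic plates

The generator emulates the imaging situation the pipeline was designed
for: transmissive backlight, true grayscale sensor, ≈ 40 µm/px so that
0.5 mm colonies are resolved, 8-bit depth.

* **Background**: level 230 of 255 plus a random low-order polynomial
  field of amplitude ±15 (variable broth-layer thickness), plus additive
  Gaussian sensor noise σ = 3 rounded to integers — a small fraction of
  colony contrast, as a properly exposed backlit image gives.
* **Colonies**: circles with diameters uniform in 0.5–2.0 mm (24 h
  colonies; up to 4 mm remains within the rolling-ball budget), radial
  darkness profile `depth · (1 − (d/r)²)^p` with p = 0.5 — a
  hemispherical dome whose footprint spans the full nominal diameter
  and whose center is the unique darkest spot.
* **Darkness**: the center depth is drawn once per plate from 60–140
  gray levels, with ≤ 8 % per-colony jitter. One plate carries one
  strain at one incubation age, so colony opacity is a plate-level
  property; the 60–140 spread models between-plate variability
  (organism, medium, exposure). This matters: the contrast stretch
  normalizes each plate by its deepest colony, so a counter set up with
  a fixed brightness lift presupposes within-plate uniform opacity —
  with independently sampled depths, colonies shallower than roughly
  57 % of the plate's deepest would be pushed above the lift threshold
  and silently lost. The pipeline (like the fixed parameter set it
  reproduces) is validated for uniform-opacity plates.
* **Overlap**: where colonies touch, darkness composes as the pointwise
  *maximum* of the two profiles, not the sum — colonies are opaque
  bodies that abut, each keeping its own darkest center, rather than
  transparent films that stack. Additive composition would make the
  contact zone darker than either center at ≳ 30 % overlap and merge the
  pair into one minimum, contradicting the observed behavior of real
  clustered colonies.
* **Placement**: uniform rejection sampling inside the ROI, whole
  colony inside the region, pairwise center separation ≥
  `min_separation_mm` (default twice the maximum diameter: the "well
  separated" regime); 10⁴ attempts per colony, then a hard
  `PackingError` — never silent truncation.

Generation is a pure function of the spec (seed included): identical
specs give byte-identical images.

What the generator does **not** emulate: bubbles and foreign particles
in the agar (avoided by plate preparation, and explicitly out of scope
for compensation), colony shape irregularity, halos/refraction rings,
and vignetting beyond the polynomial field. Passing the recovery suite
therefore demonstrates correctness of the *pipeline mechanics* on
images satisfying the stated assumptions, not robustness to dirty
plates.

## Confluence behavior

Two equal colonies rendered at center distance `(1 − f)(r₁ + r₂)` are
counted as 2 up to f ≈ 0.5 and merge into one count by f ≈ 0.7 (the
narrow dark seam between cores is resolved by the median filter's area
selectivity until the cores themselves fuse). The transition point is a
*characterization*, not a contract; only f = 0.3 → 2 is asserted.

## Method-comparison statistics

The benchmark table holds 25 samples, each enumerated three times by
three methods; counts are full-plate equivalents. Because 10 of 25
gold-standard samples (and all automatic counts) have zero standard
deviation, per-point error weighting is impossible; instead each axis
receives an average relative error: cv_x = 1 % (gold standard), cv_y =
5 % (manual) or a nominal 0.1 % (automatic, which is deterministic).
The slope of `y = b·x` is found by minimizing the effective-variance
chi-square; with one free parameter a bounded scalar minimization
(tolerance 1e-10) is used — any descent method finds the same minimum,
verified against a dense grid search to 4 decimals. The 95 % interval
is `b ± 1.96·SE` with SE from the chi-square curvature at the minimum
(Δχ² = 1). The original analysis does not state its interval
construction, so the reference intervals (0.972, 0.98) and
(0.896, 0.93) are reported alongside, not asserted; the curvature-based
intervals agree to ~0.002. Correction factors are computed from the
slope rounded to its reported 3-decimal precision (1/0.976 = 1.025,
1/0.913 = 1.095), matching how a reader would derive them. Reported
rounding: slopes/factors 3 decimals, variation coefficients whole
percent, rates 1 decimal. Summary means over the table are simple
(unweighted) row means.

One transcription note: benchmark sample 7's printed count ratios (0.91
auto/gold, 0.88 manual/gold) are inconsistent with its own counts
(566/579.0 = 0.98, 547.7/579.0 = 0.95); the counts — which reproduce
every aggregate statistic — are taken as authoritative and the ratio
check exempts that row.

## Test sizing

The recovery suite enumerates 50 seeded plates on a scaled-down dish
(countable radius 235 px ≈ 9.4 mm at 40 µm/px, 632×632 frames) with
5–12 colonies each — the default 4 mm separation bounds the feasible
density at this dish size — asserting exact recovery on ≥ 95 % of
plates and mean absolute relative error ≤ 2 %. Operator correctness is
additionally pinned by exhaustive brute-force oracles (explicit
footprint scans for the median, threshold-flood persistence for the
minima detector) on 100 random 32×32 images each.

## Known limitations

* Plates violating the darkest-spot premise (translucent centers,
  ring-shaped colonies) will be miscounted; the parameter set must be
  re-validated per organism and imaging setup.
* A featureless ROI is recognized by the dynamic-range guard; a ROI
  containing *only* objects shallower than the guard (< 32 levels after
  background subtraction) would be declared empty.
* The rolling-ball border policy (edge replication) leaves a concave
  kink at frame borders on strongly sloped backgrounds; countable
  regions should stay a ball radius away from the frame edge, which the
  rim inset normally ensures.
* Counts are integers and the pipeline is deterministic, so no
  uncertainty is attached to a single plate's count; uncertainty enters
  only at the method-comparison level.
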