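# Methods

This note records the models, numerical choices and limitations behind
`chorodig`, a pipeline for converting choropleth map images into GIS class
layers and population statistics.

## Georeferencing

A scanned map carries no projection. Ground control points — pixel
locations matched to projected coordinates (we default to the USA
Contiguous Albers Equal Area Conic, USGS version, carried as the opaque
identifier `EPSG:5070`) — determine a polynomial transform of order 1–3,
fitted by ordinary least squares per axis over all monomials
`col^i·row^j`, `i + j ≤ p`. Orders 1/2/3 need 3/6/10 points; with exactly
that many non-degenerate points the fit interpolates (RMS ≤ 1e-6 m). No
outlier rejection is attempted; the RMS residual over the GCPs is reported
instead, which is the honest summary when control points come from
hand-matching county corners. A polynomial of order > 1 has no closed-form
inverse, so the map→pixel direction is fitted to the same GCPs; it is
best-effort, because a configuration can determine the forward map while
being rank-deficient in map space (the inverse is only needed for
warping).

Resampling is **nearest-neighbor only**. The downstream classifier depends
on the image containing only (degraded versions of) the legend palette;
bilinear or cubic interpolation would synthesize intermediate colors that
belong to no class. Pixel coordinates are 0-based `(col, row)` with the
geotransform anchored at the outer corner of pixel (0, 0) and pixel
centers at half-integer offsets; world files (which reference the first
pixel *center*) are converted on read/write.

Raster I/O uses TIFF (with basic GeoTIFF pixel-scale/tiepoint tags for
north-up grids) and PNG/JPG, always with an ESRI world-file sidecar plus a
small JSON sidecar carrying the CRS identifier. Vector zone layers are
GeoJSON. No datum transformations are performed anywhere: the CRS is an
identifier the caller must keep consistent, and an equal-area projection
is assumed wherever pixel counts become areas.

## Multiresolution segmentation

The central primitive. Every valid pixel starts as its own object; the
heterogeneity of an object is `h(O) = Σ_b w_b · n·σ_b(O)` (population SD
per band, band weights `w_b`, default all 1), and the cost of merging A
and B is the heterogeneity increase

    Δh = h(A∪B) − h(A) − h(B)  ≥ 0.

A merge executes only when Δh < s² (scale parameter `s`) **and** the pair
is a mutual best fit — each is the other's minimum-cost neighbor. Passes
over all objects repeat until a pass makes no merge.

Determinism is a design requirement: objects are visited in ascending id,
cost ties break to the lower neighbor id, and a merged object keeps the
smaller id, so a segmentation is bit-reproducible. Statistics are
maintained incrementally from per-object sums and sums of squares; because
pixel values are integers, these sums are order-exact in float64, and the
independent reference implementation (`chorodig.reference`, which
recomputes every statistic from the raster) produces bit-identical costs —
the test suite exploits this for exact partition equality on exhaustively
enumerated small images.

Choices worth recording:

- **Color-only cost.** No shape/compactness term: on flat-palette
  choropleth maps shape terms add nothing and would break the simple
  variance decomposition.
- **4-connectivity** by default, so 1-pixel black border lines are not
  leaked across diagonally.
- **Population SD** (divide by n), consistent between the merge cost and
  the exported object statistics.
- **Default scale s = 10** (threshold s² = 100 in summed 8-bit SD units).
  On a degraded palette map this lets same-class noisy pixels coalesce
  (typical single-pixel merge cost ≈ 3 bands × |Δ| ≈ 10–40) while keeping
  class boundaries apart (cross-class costs are hundreds). A small scale
  deliberately over-segments blurred boundaries rather than creating
  mixed-color objects.
- Merge cost of two solid half-planes of black and white: ≈ 765·n, far
  above any sensible threshold — uniform regions merge internally first,
  then stop at the boundary.

Complexity is effectively linear in pixels for palette maps (object count
roughly halves per pass); a 600×400 scene segments in a few seconds.

## Color-threshold backend

The lighter alternative: a pixel within `tolerance` (max per-band absolute
difference, default 30) of a legend color takes that class directly;
legend colors must be separated by more than twice the tolerance so the
match is unique. Remaining unassigned pixels form "holes":

- a hole enclosed by a single class is filled with that class as a whole;
- a hole touching several classes — in practice a band of blur-mixed
  colors running *along* a class boundary, often straddling both sides of
  a black border line — is resolved **per pixel**, each pixel taking the
  touching class nearest to its own color (ties: longest shared hole
  boundary, then lowest class id).

The per-pixel rule for multi-class holes is a deliberate design choice:
assigning such a band to a single nearest class would hand the entire
boundary band to one side and systematically destroy the other side's
edge pixels; per-pixel assignment splits the band along the true boundary.
Single-class enclosures (true holes) keep the simpler whole-hole fill.

## Object classification

Objects are classified by a random forest over six features — per-band
color mean and SD. Defaults: 500 trees, √6 features per split, unlimited
depth, out-of-bag accuracy reported, mandatory seed. The forest is a
standard component (scikit-learn's `RandomForestClassifier` behind a
sklearn-compatible `ObjectColorClassifier` estimator); the pipeline's
contribution is everything around it. Every object receives its
majority-vote class with no probability thresholding; per-object vote
fractions are exportable for manual review. The pixel class layer is
derived from object classes by lookup, so pixel and object layers can
never disagree.

## Ink cleanup

Published maps carry black county borders and name labels. Cleanup runs in
two stages on objects currently classified as the black ink class:

1. **Small objects** (≤ 5 px by default — label fragments): reassigned to
   the colored class holding the greatest *shared boundary length* among
   non-black neighbors. Boundary length, not neighbor count, so a 1-px
   sliver neighbor cannot outvote a long edge.
2. **Line work**: dissolved by iterative boundary absorption — each pass,
   every black pixel adjacent to a colored pixel takes the colored class
   with the most adjacent colored pixels (ties: lowest class id), also
   adopting the lowest adjacent object label of that class so the
   pixel/object agreement survives. This is the geodesic-nearest-class
   completion of the line; it terminates when no black pixels remain, and
   any unreachable leftovers (black enclosed entirely by no-data) become
   no-data with a warning.

Because the black *class* (not black color) defines the work list, the
operation is idempotent, conserves the classified+nodata pixel count, and
leaves no black-classified pixel behind. An analogous fill-from-fallback
operation borrows classes from a companion map inside listed units (used
when one map's source agencies did not report and a near-in-time map can
stand in); provenance tags (`model` / `rule` / `override` /
`fallback-map`) record how every object got its class.

## Zonal summaries

Class areas per county use the pixel-center rule: a pixel belongs to the
unit containing its center. At equal-area resolution this is unbiased and
deterministic; exact polygon clipping is deliberately out of scope.
Percentages are relative to the unit's **official** area (not the
classified area), so partially mapped counties show low coverage rather
than inflated class shares. A county's majority class is retained only
when it beats the runner-up by strictly more than the margin (default 25
percentage points — the canonical comparison is 45 % vs 20 %, margin
exactly 25, which *fails* the strict test) and when at least 25 % of the
county carries any density class. Only density classes compete; no-data
and ink never hold a majority. Change analysis between two maps categorizes
units valid in both as decreased / same / +1 / >+1 by ordered class-index
difference; units valid in only one map are reported separately, never
forced into a category.

## Populations, calibration, comparisons

Populations are linear in class areas: `P = Σ_c A_c·v_c` over density
classes, where the upper three classes carry their interval lower bounds
(5.8, 11.6, 17.4 deer/km²) and the open-ended low class is calibrated by
the exact linear solve `v_free = (T − Σ v_c·A_c)/A_free` against a known
total `T` (≈30 million deer at 2000 yields 1.85 deer/km² for the 2003
map). A negative solution is returned but flagged. Statewide density
divides by the official state area; presence density divides by summed
presence-class area. Comparison statistics follow the reported−map sign
convention, quotients are reported at 2 decimals, multi-year agency series
use the sample (n−1) SD, and threshold counts ("states at ≥ 9.8 deer/km²")
compare densities rounded to 0.1, matching how such tables are printed.
Raw unrounded values are retained everywhere; rounding is reporting-only.

The bundled CSVs transcribe the published per-state tables (QDMA 2005
estimates, Southeast Deer Study Group 2001–2005 annual estimates, and the
population/density/presence-area table for the digitized 1982 and 2003
maps). Two obvious typesetting glitches were repaired during transcription
(a misplaced comma in New York's 2003 area, read as 126,570 km²; a missing
comma in Ohio's 2003 population, read as 547,460). One internal
inconsistency in the source material is noted rather than resolved: the
running text calls 7.2 deer/km² "Georgia, 1982" while the table prints
Georgia 4.7 and Alabama 7.2; the tables are taken as authoritative.
The per-state total areas behind published statewide densities come from
the original authors' unpublished county layer; any equal-area US layer is
acceptable input, so statewide densities computed here may differ in the
last digit for states far from full coverage.

## Synthetic maps and what passing tests show

The generator emulates the scan the pipeline expects: a Voronoi
tessellation of `n_units` seed points clipped to the extent, unit classes
drawn iid from `class_probs` then smoothed by neighbor-majority passes
(spatial coherence), legend-colored fills, 1-px-and-up black borders,
small black glyph blocks standing in for county names (what matters for
cleanup is small black foreign objects, not letterforms), then Gaussian
blur and additive Gaussian noise. Defaults — 600×400 px at 1 km/px, 30
units, four classes with probabilities (0.4, 0.3, 0.2, 0.1), one
smoothing pass, border width 1, ~2 glyphs/unit, blur σ 0.5 px, noise SD 4
— model a small published national map scan of moderate quality. All
stochastic steps derive from a single seed; generation is bit-reproducible.

Ground truth records each pixel's *underlying* class (border and glyph
pixels carry their unit's class) alongside the *rendered* category
(including ink), which is what a human labeling training objects sees.
Training sets for synthetic runs sample 10 % of objects and label them by
majority rendered category, topping up any missed class with its largest
object.

What the generator does **not** model: JPEG blocking and other compression
artifacts, fold lines, moiré, uneven illumination, anti-aliased text, or
legends with low-contrast/overlapping colors. Passing the synthetic
recovery checks (≥99 % pixel accuracy and all unit majorities for the
OBIA backend; ≥98 % for the threshold backend) therefore demonstrates the
machinery is correct under blur+noise degradation with a well-separated
palette — not that any particular historical scan will digitize at that
accuracy. Real scans need the manual-override hook for stubborn boundary
errors, exactly as printed-map workflows do.

## Numerical and testing notes

- Segmentation ties and visit order are fully specified (see above), so
  partitions are comparable across machines.
- The oracle-equivalence acceptance test enumerates **all** two-color
  images up to 4×4 (65,536 patterns at a scale exercising both merge
  regimes, plus both scales for every smaller shape) and random 3-color
  5×5 images; in pure Python this takes a few minutes and dominates the
  suite's runtime.
- The end-to-end acceptance checks run at the full 600×400 / 30-unit
  default conditions; the rest of the suite uses a 150×100 / 8-unit scene
  for speed.
- Degenerate inputs are contracts, not crashes: empty or all-nodata
  images, zero-area free class in calibration, overlapping legend colors
  under the threshold tolerance, unit-id mismatches in change analysis and
  unknown override targets all raise with actionable messages; black
  pixels no absorption can reach become no-data with a warning.
- Shapefile/GeoPackage I/O is not implemented (GeoJSON covers the vector
  contract); there is no OCR of map text, no GUI, and no multi-level
  segmentation hierarchy.
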