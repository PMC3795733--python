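# Methods

This note documents the measurement model, the numerical choices behind
each estimator, the synthetic-data model used for validation, and the
known limitations.

## Segmentation model

A field is an 8-bit RGB raster with a known pixel pitch (default
0.34 µm/px; the default 1813×1813 px field covers 0.38 mm²).  Stain
detection combines two tests per pixel:

* **darkness** — intensity (mean of the RGB channels) below a per-image
  dynamic threshold.  Otsu's method on the intensity histogram is the
  default because it is parameter-free; a percentile threshold is
  available in `SegmentationConfig` for images whose stained fraction is
  far from Otsu's bimodality assumption.  A (near-)uniform image has no
  meaningful dynamic threshold: the mask is empty and a warning is issued.
* **hue** — pixels whose HSV hue falls in the haematoxylin band, default
  [180°, 280°] (blue through purple counterstain), are rejected whatever
  their darkness.  DAB brown sits near 20–40° and passes.

Stained objects are 8-connected components; their gaps (enclosed
background) are 4-connected — the standard dual pairing that avoids
topological paradoxes.  A gap at least 1.0 µm wide is a lumen; narrower
gaps are artefacts and are filled into the stain.  Background touching the
object's bounding region border is open background, never a gap, so no
border-touching region can ever become a lumen.  An object whose filled
set (stain plus lumens) is at least 3.5 µm wide is a microvessel; width is
everywhere the diameter of the largest inscribable circle, computed as
twice the maximum of the Euclidean distance transform.  The same width
definition is applied to gaps — width is defined once in this pipeline and
used uniformly.

Border-touching vessels are retained by default (hot-spot photographs crop
vessels at the frame; discarding them would bias the size markers
downward); `keep_border_vessels=False` is available.

## Per-vessel estimators

**Areas** are pixel counts times pitch²; vascular = endothelial + luminal
holds exactly by construction.

**Outer perimeter** is measured on the filled set only, so lumen
boundaries never contribute.  The boundary is traced as a closed
8-connected Moore chain.  Plain chain weights (1 per axial step, √2 per
diagonal step) systematically overestimate smooth boundaries — about +5%
on digital circles, the classic staircase bias — so the default weights
are the Vossepoel–Smeulders calibrated pair (0.948, 1.340), plus a +π px
offset because the chain runs through boundary-pixel centres, half a pixel
inside the true boundary (offsetting any simple closed curve outward by
½ px adds exactly π px of length, its total turning being 2π).  Measured
error on digital discs of radius 30–80 px is below 1.2%.  The plain scheme
remains available as `method="chain"`.  A single isolated pixel is scored
as its unit pixel square, 4·pitch.  The corrected weights are calibrated
for smooth boundaries and underestimate long axis-aligned straight edges
by up to ~5%; vessel profiles are smooth, so this trade-off is the right
one here.

**Solidity** is filled area over the area of the rasterized convex hull
(`skimage` convention).  No raster hull estimator can be unbiased for both
smooth shapes and pixel-tiling shapes: for a smooth profile the corner
hull carries a dilation band of roughly 0.4 px per boundary unit that the
object's pixel count does not, while for axis/diagonal-aligned tilings it
carries none, and the raster does not reveal which case applies.  The
resulting bias is O(perimeter/hull area): about −0.04 for a 15 px-radius
disc, −0.02 at 25 px, −0.01 at 40 px; it is documented rather than
corrected.  Degenerate one-pixel-wide objects whose hull collapses get
solidity 1.

**Skeletons** come from topology-preserving thinning
(`skimage.morphology.skeletonize`); length sums inter-pixel steps (1 or
√2) times pitch.  A branch point is a skeleton pixel with ≥3 skeleton
neighbours (8-connectivity); thinning produces adjacent triple points at
real bifurcations, so branch pixels within a 2 px radius are merged into
one branch point.

**Centroid** is the centre of mass of the filled pixels — the standard
"centre" choice; for crescent-like profiles it may fall outside the
filled set, which is acceptable for centre-to-centre distance statistics.

## Field-level markers

Size and shape markers are plain means/sums over the vessel population;
MVA_CV uses the sample (n−1) standard deviation.  Markers that are
undefined at the observed vessel count (means need ≥1 vessel; MVA_CV and
ICD need ≥2) are reported as missing (NaN), never as zero.

**MVA_rx4** slides an axis-aligned window with linear dimensions ¼ of the
field's (a subfield at 4× magnification) across the field with stride
window/8 (sliding rather than tiled: it upper-bounds the tiled maximum and
is stride-robust) and reports total vascular pixels over the best window's
vascular pixels.  The value lives in [1, 16] up to window discretization.

**MV_scale** measures how the skeleton mass within a window scales with
window size.  Fifty window sizes are geometrically spaced from 3 px to the
image height (geometric spacing so the log-log fit is not dominated by
large sizes); 200 windows per size are placed uniformly at random fully
inside the field (seeded); the skeleton content is averaged over
*non-empty* windows only, and the slope is a single ordinary
least-squares fit of log mean content against log size.  The non-empty
conditioning is essential: unconditional averaging makes the expected
content proportional to s² for *every* pattern, so every pattern would
score 2.  Conditionally, a space-filling mask scores 2, a single straight
line 1, an isolated point 0, and clustering a fixed stroke mass raises the
slope.  Sizes at which every window is empty are dropped; fewer than two
usable sizes yields a missing value.

**ICD** builds the Gabriel graph on vessel centroids: points u, v are
neighbours iff no third point lies in the closed disc on the segment uv.
The closed-disc tie rule is degenerate-safe and reproducible (a point
exactly on the circle blocks the edge — so the corners of a square are
joined by its sides and not its diagonals); exact duplicate coordinates
are jittered by 10⁻⁶ px with a seeded RNG.  Candidate edges come from the
Delaunay triangulation (the Gabriel graph is a Delaunay subgraph);
collinear point sets, where the triangulation does not exist, fall back to
an all-pairs check.  ICD is the mean edge length between centre points
(not boundary-to-boundary distances), in µm.

## Synthetic fields

Each vessel is a continuum shape built from densely sampled generating
curves (shapely polygons; buffered arcs at 64 segments per quarter turn,
a polygonal oracle at far finer than raster resolution): solid or ring
annuli, elliptical rings of uniform wall thickness, buffered wavy ribbons
(open or closed into tubes), and branched unions of radiating strokes.
Ground truth — areas, outer perimeter, solidity, largest-inscribed-circle
width, centroid — is read directly off the continuum geometry, so
raster-side estimators can be tested for convergence (mask areas agree
with continuum areas within 3% for vessels at least 20 px wide, improving
with size).  MVA_rx4 and MV_scale have no closed continuum form; their
ground truth is computed from the ground-truth masks by the same
definitions as the measurement module.

Rendering paints vessel walls in DAB brown (HSV ≈ 27°, 0.70, 0.42), lumens
and background near-white, and haematoxylin nuclei in blue (≈ 230°), with
small additive Gaussian pixel noise (σ = 0.008); a pixel belongs to a mask
iff its centre lies inside the continuum polygon.  The same spec and seed
render bit-identically.  Noise specks are DAB-coloured discs below the
3.5 µm width rule, placed away from vessels so that no speck can bridge
an object across the width threshold.  Vessels are placed by rejection
sampling with non-overlapping bounding discs (per-vessel ground truth
stays unambiguous); an infeasible density raises a placement error.

Default study conditions, chosen once: 1813×1813 px at 0.34 µm/px
(0.38 mm² field), 25 vessels per field (≈66/mm²), mean outer radius 25 px
(≈17 µm diameter, giving a mean outer perimeter near 53 µm, consistent
with the default cohort marker scale), lumen probability 0.5, 40 specks.
Within-vessel stain intensity is uniform — real DAB is heterogeneous; this
is a deliberate simplification, so segmentation tests exercise the
darkness/hue logic, not robustness to stain texture.  What passing tests
show is therefore that the geometry pipeline is correct and calibrated;
they do not show robustness to out-of-focus regions, stain heterogeneity,
overlapping vessels, or CD34-positive stromal fibrocytes (excluded by
design here as in practice by case selection).

## Synthetic cohorts

Event times follow a proportional-hazards model with exponential baseline:
patient i's hazard for an endpoint is λ₀·exp(Σ_m β_m z_im) with z the
standardized markers and β the true log hazard ratios per SD.  The
exponential baseline is the simplest model satisfying the proportional-
hazards assumption that the Cox analyses make.  Censoring is an
independent uniform follow-up window, default 1–125 months; λ₀ is
calibrated by root finding so the marginal event fraction hits its target
(defaults 0.21 for DDFS, 0.17 for BCSS, matching a ~293-patient validation
cohort with ~61 and ~51 events).  Default marker effects are hazard ratios
per SD of 1.286/1.369 (mean perimeter, DDFS/BCSS), 0.69/0.71 (solidity),
and 0.94–1.29 for the rest of the panel.  Markers are generated
independently — adequate for effect-recovery and error-rate validation,
but real vascular markers are correlated, so multi-marker joint behaviour
on real data is not represented.  The two endpoints are simulated
independently given the linear predictors.

## Panel statistics

Continuous screening standardizes each marker (sample SD, complete-case)
and fits a univariate Cox model per endpoint (lifelines, Efron ties); the
Bonferroni gate passes p ≤ α/m with α = 0.05 and m the panel size (7 →
0.0071), non-strict inequality; a marker is prognostic only if it passes
for both endpoints — a rule strictly more conservative than either
endpoint alone.  Median dichotomization sends ties at the median to the
low group (an odd n splits (k+1)/k, e.g. 293 → 147/146).  Exact
association tests draw ≥10⁵ Monte-Carlo tables from the conditional
distribution given the margins (Patefield's algorithm, seeded) and use the
Pearson χ² statistic, or the linear-by-linear statistic (n−1)·r² with
integer scores for ordered covariates; the p-value uses the standard
(hits+1)/(draws+1) estimator.  Multivariate Cox fits warn below 10 events
per variable.  A seeded 25/75 pilot/validation split utility is provided
for study designs that select markers on a pilot subset.

Simulation loops (HR-recovery replicates, the 500-replicate family-wise
error check of the panel gate) use an internal Newton solver for the
single-covariate partial likelihood on untied times, where Breslow and
Efron coincide; it is cross-checked against lifelines to 10⁻⁵ in the test
suite.  The HR-recovery oracle (true HR/SD 1.4 at n = 400, estimates
within [1.2, 1.6]) is run at 50% censoring: the band corresponds to about
±1.9 standard errors at ~200 events, so that condition makes the stated
≥80% in-band rate attainable with margin, whereas at the cohort default's
~84 events the band is only ±1.2 SE and the expected in-band rate falls
below 80%.

## Problem sizes

The validation suite uses 20 full-size rendered fields for marker
recovery, 600 px masks for the scaling-limit checks, 50 replicates for HR
recovery, 500 for the family-wise error rate, and 40 for subgroup-pattern
recovery — sizes at which every Monte-Carlo margin above is comfortable
while the whole suite stays in the minutes range on one CPU.

## Known limitations

* The dynamic darkness threshold is Otsu's method; the original
  acquisition software's exact dynamic thresholding is not public, so
  absolute stain masks on real images may differ even though the
  downstream rules (1.0 µm, 3.5 µm, inscribed-circle width) are exact.
* Perimeter and solidity carry the small raster biases quantified above;
  comparisons *between* fields measured with the same estimators are
  unaffected.
* Whether the original system measured gap width by inscribed circle, and
  whether its subfields were tiled or sliding, is not documented; the
  choices here (uniform width definition; sliding windows) are the
  parsimonious ones and are configurable where they matter.
* The cohort generator is a validation instrument, not a disease model:
  exponential baselines, independent markers, independent censoring.
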