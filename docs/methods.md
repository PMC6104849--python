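# Methods

`viewscape` maps where a landscape is *seen from* rather than where
photographs cluster.  Given geotagged photo locations and a
LiDAR-style surface model, it computes one viewshed per photo, overlays
them into a per-cell **viewshed intensity** count, validates photo
content against the land cover visible from each point, and models the
intensity counts with a negative-binomial regression on landscape
covariates.  This note records the models, the numerical choices, what
the synthetic scene does and does not emulate, and the known
limitations.

## Surface model

The DSM is built by **max-Z binning**: each cell takes the maximum
return elevation among the points that fall in it.  Cell membership
uses half-open intervals with the origin at the lower-left corner; a
point on a shared edge belongs to the cell with the larger row/column
index, and row 0 is the southernmost row internally (writers emit the
conventional north-first ESRI ASCII row order).  Returns above a noise
cap (default 300 m, appropriate for a low-lying coastal plain) are
*deleted before* the maximum, not clamped: spuriously high returns are
outliers, and clamping would plant phantom towers.  Cells with no
surviving return are nodata.  Because the maximum is over the first
(all-surface) returns, canopy and buildings are part of the surface —
this is a surface model, not a bare-earth terrain model.

Voids are left as nodata by default (`fill_nodata(policy="none")`);
the nearest-neighbour fill policy (ties broken by smaller row, then
smaller column, so results are order-independent) exists because the
viewshed engine refuses to stand an observer on a nodata cell.

Slope uses Horn's 3×3 operator, the raster-GIS standard, in degrees.
Border cells use edge replication, which flattens the one-sided
gradient there — slope is a regression covariate, and a biased border
ring of one cell is preferable to propagating nodata inward.

## Viewshed semantics

The package defines one normative line-of-sight rule and implements it
twice — a compiled kernel (`viewshed`) and a plain-Python per-target
oracle (`viewshed_naive`) that must agree **exactly**, bit for bit:

* the observer stands on the surface model at
  `dsm(observer cell) + eye height` (default 1.6 m, an assumed human
  eye level).  Standing *on* the surface is a deliberate, documented
  semantic of a DSM-based analysis: an observer inside a forest stands
  on the canopy.  It overstates visibility under trees and is the main
  caveat of the approach;
* targets are evaluated centre-to-centre within an inclusive maximum
  range (default 3 km);
* the sight line is sampled every `cellsize/2`; terrain at a sample is
  the value of the containing cell (nearest-cell lookup); samples
  inside the observer or target cell are excluded;
* the target is visible iff the maximum sample tangent `(z_s − z_o)/d_s`
  does not exceed the target tangent.  Tangents are used instead of
  angles (strictly monotone equivalent, no trig); **ties pass** —
  a grazing ray counts as visible;
* nodata samples neither occlude nor are visible as targets;
* Earth curvature and refraction are ignored: the curvature drop at
  3 km (≈0.7 m) is below the surface noise floor.

Half-cell sampling is a resolution choice, and decisions within a
narrow tangent band (|margin| of order 0.01–0.02 on rough unit-cell
terrain) are resolution-limited: a finer sampler can flip them.  The
test suite therefore checks exact agreement against a `cellsize/8`
dense-sampling oracle only outside that band, and exact agreement
between the two same-resolution implementations everywhere.

Multiple photos in one cell produce identical masks but are counted
separately in the overlay — duplicate locations are kept deliberately,
since de-duplication would discard genuine repeat appreciation.

## Intensity, composition and content validation

The intensity surface is the per-cell count of overlapping viewshed
masks.  The conservation identity
`sum(intensity) = sum(per-photo visible counts)` is asserted on every
pipeline run.  Land-cover composition within a viewshed is the fraction
of visible non-nodata cells per class; coarser categorical rasters are
nearest-neighbour resampled to the DSM grid (categorical codes must
never be averaged).

Content validation treats each land-class tag as a pair of binary
raters — "the photo shows class X" vs "class X is visible from the
photo point" — and reports percent agreement and Cohen's kappa per
class (a single multi-category kappa would hide which classes
disagree).  Viewshed presence defaults to "any visible cell"
(`min_fraction = 0`), configurable, since no threshold is canonical.
The tag-to-code mapping ships as an editable table
(`validation.DEFAULT_TAG_TO_CODES`).  Relevance filtering applies only
to validation and reporting, never to the intensity overlay: the
non-relevant fraction is small and visibility is content-agnostic.

## The count model

Intensity counts are overdispersed (many zeros, a few very large
values), so the model is NB2 with a log link:

    y_i ~ NB(mu_i, alpha),  ln mu_i = x_i' beta,  Var(y_i) = mu_i + alpha mu_i^2

Fitting profiles beta out at fixed alpha by IRLS (working weight
`mu/(1+alpha*mu)`, step-halving so the accepted deviance path is
non-increasing; convergence when the relative deviance change drops
below 1e-8, max 100 iterations, link-scale values clipped at ±30 to
guard against separation).  Alpha is selected by a systematic scan —
AIC over a 31-point log-spaced grid on [1e-3, 1e2], then golden-section
refinement of log(alpha) between the flanking grid points to a relative
tolerance of 1e-4.  The selected AIC is asserted to be no worse than
every grid candidate.  On equidispersed data the AIC profile is flat
below alpha ≈ 1e-2, so "alpha at the lower bound" means anywhere in the
bottom decade.

Standard errors come from the observed information
`sum x x' mu (1+alpha*y)/(1+alpha*mu)^2`; p-values are Wald, with no
multiple-testing correction.  Reported per-covariate quantities:
incidence-rate ratio `exp(beta_j)`, and the standardized estimate
`beta_j * SD(x_j)/SD(y)` — the linear-model convention applied to the
raw response, approximate in a GLM but directly comparable across
covariates.  Fit quality is McFadden `1 − lnL1/lnL0` and Nagelkerke
`[1 − (L0/L1)^(2/n)]/[1 − L0^(2/n)]` against an intercept-only null
fitted by the same alpha-selection procedure.

Covariates follow a fixed schema: binary class indicators (forest,
agriculture, fresh water, ocean, woody and emergent wetland, urban,
park, trail buffer), natural-log distances (+ one cell size as offset,
so `ln(epsilon)` is the value on the feature) to the coastline, lake
shorelines, coastal attractions and historical attractions, terrain
slope, and population density.  The trail buffer defaults to 100 m
(configurable — sources differ between 50 and 100 m, and the wider
buffer matches the coefficient naming used in reporting).  The sampled
covariate table carries a provenance sidecar (seed, fraction, layer
checksums) and the sample is drawn uniformly without replacement,
`round(fraction × N)` cells, default 1%.

Diagnostics: definition-based VIF (flagged above 10; exact collinearity
reported as infinite, not raised), and a global Moran's I of Pearson
residuals with row-standardised k-nearest-neighbour weights (k = 8 —
no weights scheme is canonical, and kNN is robust to irregular sample
geometry; rook contiguity is available for gridded inputs) and a
seeded two-sided permutation p-value (999 permutations).

## The synthetic scene

No public archive of the original study inputs exists, so the package
ships a generator whose outputs have known ground truth.  The default
scene is desk-scale: 200×200 cells at 6.096 m (≈1.2×1.2 km) — small
enough for the naive viewshed oracle to be usable in tests, rich enough
to give every covariate real variation.  It contains ocean and a beach
with a dune ridge on the east, a lake, forest (with +14 m canopy),
farmland, woody (+10 m) and emergent (+1.5 m) wetland, an urban block
with seeded 4–12 m buildings, a 25 m monument knoll inside a park, a
second shoreline park, trails, two piers and a monument point, plus a
population-density blob over the urban core.  The point cloud samples
the analytic surface on a jittered dense lattice (4 points/cell,
z-noise SD 0.05 m) with 20 injected high-noise outliers above the cap;
the land-cover raster is generated 5× coarser than the DSM to exercise
categorical resampling.  Everything is a pure function of (spec, seed):
equal seeds give byte-identical outputs.

Photos (default 2000) are placed over cells with probability
proportional to `exp(x' beta*)`, with `beta*` following the fitted
coastal-landscape pattern (strong positive ocean effect, negative
wetland/forest/agriculture and log-distance effects) and `alpha* = 0.5`
(moderate overdispersion).  Labels are read off each photo's true
viewshed composition and flipped symmetrically with probability 0.2;
12–13% of photos are injected as non-relevant with empty labels.
`make_counts` draws NB2 counts by the exact gamma–Poisson mixture,
verifiable by moments.

**What passing tests show, and what they do not.**  The synthetic chain
closes the loop in two senses.  (1) Counts drawn from the assumed NB
law on the real scene covariates recover every generating coefficient
of magnitude ≥ 0.3 with the right sign at n = 5000, and `alpha*` within
[0.4, 0.6] — the estimator is sound.  (2) The genuine photo → viewshed
→ overlay → fit route recovers the *named strong effects* (ocean
positive, woody wetland negative).  It cannot recover every
placement coefficient's sign, and that is physics, not a bug: with a
3 km view range on a ~1.2 km scene, open flat areas (the lake surface)
are visible from nearly everywhere, so their overlay intensity is high
even when photographers avoid them.  Viewshed intensity measures
*being seen*, which is related to, but not identical with, *being
photographed from*.  Real deployments, where the study region is much
larger than the view range, sit between these regimes.  The synthetic
scene also does not emulate GPS error, user clustering by personality,
seasonal variation, or photo orientation.

## Numerical and degenerate-input conventions

* Non-finite cloud records are rejected with a structured warning
  carrying the count, never dropped silently.
* An empty cloud bins to an all-nodata grid; an all-nodata grid cannot
  be nearest-filled (error).
* Cohen's kappa: chance agreement of exactly 1 (both raters constant
  and equal) returns kappa = 1; in a 2×2 table this is the only way
  `p_e = 1` can arise, so the "undefined kappa" guard is unreachable
  but kept.
* Composition of a viewshed with zero visible data cells is an error,
  not an empty record.
* Sample standard deviations throughout (population SD available by
  flag); a single-record composition summary reports SD 0 by
  convention.
* ESRI ASCII grids are written at `%.17g` so file round-trips are
  bit-exact, including georeferencing.

## Known limitations

* Observer-on-canopy semantics (see above).
* The naive oracle is O(cells × range) per photo and intended for
  ≤ 256×256 grids; the compiled kernel is the production path.
* The standardized-coefficient convention is a linear-model
  approximation on a GLM scale.
* Reported `exp(beta)` values for log-distance covariates are per-unit
  effects of the *logged* distance and do not translate into "per km"
  statements without fixing a reference distance; the package reports
  `exp(beta)` as computed and leaves such narrations to the analyst.
* Travel-time and fishing-location covariates, TIN interpolation,
  return classification, distance-weighted visibility and automated
  image classification are out of scope.
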