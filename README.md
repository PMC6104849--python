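# viewscape

Viewshed-intensity mapping and negative-binomial modelling of cultural
ecosystem services (CES) from geotagged photo locations.

Landscapes provide non-material benefits — scenery, recreation,
heritage, sense of place — that are hard to measure at landscape scale.
Geotagged photos volunteered on social media are *in situ* evidence of
appreciated places, but a photo point alone ignores what the
photographer could actually see.  `viewscape` implements the
viewshed-intensity approach for researchers in landscape ecology and
geoinformatics: from a LiDAR-style point cloud it builds a digital
surface model (DSM), computes one viewshed per photo location, overlays
all viewsheds into a per-cell count of "how many photo points see this
cell", validates photo content against the visible land cover, and
models the intensity surface with a count regression on landscape
covariates.

The core model is NB2 with a log link,

    y_i ~ NB(μ_i, α),   ln μ_i = β₀ + β₁x_{i1} + … + β_k x_{ik},
    Var(y_i) = μ_i + α μ_i²,

where `y` is the viewshed-intensity count of a sampled cell, `x`
contains land-cover indicators, log-distances to coast/lakes/
attractions, slope and population density, and the dispersion `α` is
selected by a systematic AIC scan with golden-section refinement.
Reports include incidence-rate ratios `exp(β)`, standardized
estimates, McFadden/Nagelkerke pseudo-R², VIF screening and a
permutation Moran's I on residuals.  Photo-content validation uses
percent agreement and Cohen's kappa per land class.

Because the data source that motivated the method is defunct, the
package ships a fully synthetic coastal scene with known ground truth
(`viewscape.synthetic`) on which every stage — and the whole chain —
is exercised and tested.

## Worked example

```python
import numpy as np
from viewscape import (SyntheticSpec, make_landscape, bin_points,
                       ObserverSpec, viewshed, accumulate)

scene = SyntheticSpec()                 # 200x200 cells @ 6.096 m, seeded
land  = make_landscape(scene)
dsm   = bin_points(land.cloud, scene.grid, z_cap=300.0)

vs = viewshed(dsm, ObserverSpec(x=500.0, y=500.0))   # eye 1.6 m, range 3 km
print(vs.visible_count, round(vs.visible_area / 1e4, 1), "ha")
# 4717 17.5 ha
```

The numbers say: from a point in the open grassland, 4717 of the 40 000
cells (≈17.5 ha) are within an unobstructed 3 km line of sight on this
surface — forest canopy, buildings and the dune ridge block the rest.

The end-to-end run is driven by the numbered scripts:

```
python analysis/01_simulate_scene.py         # scene -> scratch/scene, summary -> results/
python analysis/02_viewsheds_and_intensity.py
python analysis/03_validate_photo_content.py
python analysis/04_fit_intensity_model.py
```

`04` prints the fitted model; on the default scene (2000 photos, 1%
cell sample):

```
photo-route NB fit (n=400, alpha=0.357, McFadden R2=0.210, Nagelkerke R2=0.920)
Moran's I of residuals: 0.0162 (p=0.384)
  ocean                   2.9601  irr=  19.300  p=0.0000
  woody_wetland          -1.2815  irr=   0.278  p=0.0000
  forest                 -0.6332  irr=   0.531  p=0.0000
  ...
closure fit: alpha_hat=0.491 (true 0.5); 10/10 strong coefficients recover the generating sign
```

Cells on the open sea are seen roughly 19 times more often than the
baseline (every beach photo sees a lot of ocean), woody wetland is seen
~0.28 times as often (canopy blocks sight lines), and the residuals
show no spatial autocorrelation.  The closure fit confirms the
estimator itself: counts simulated from the assumed NB law on the same
covariates give back the generating coefficients.

A CLI mirrors the stages (`ces build-dsm`, `ces viewshed`,
`ces intensity`, `ces make-synthetic`, `ces run`); see `ces --help`.

## Layout

```
src/viewscape/     library: grids, dsm, viewshed, intensity,
                   validation, regression, synthetic, pipeline, cli
analysis/          numbered narrative drivers (write results/)
tests/             pytest suite incl. end-to-end acceptance checks
docs/methods.md    models, conventions, numerical choices, limitations
```
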