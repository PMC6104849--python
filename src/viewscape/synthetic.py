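"""Synthetic coastal landscape with known ground truth.

No public archive of the original inputs exists (the photo platform is
defunct), so every pipeline stage is exercised on a generated scene
instead: an analytic terrain surface (smooth base + Gaussian bumps +
planted walls + zone-dependent canopy and buildings), a zoned land-cover
raster, vector feature layers, a population surface, and photo points
whose placement follows a log-linear intensity law with user-set
coefficients.  Everything is a pure function of (spec, seed), so equal
seeds regenerate byte-identical data.

The default scene is desk-scale — 200x200 cells at 6.096 m, about
1.2 km x 1.2 km — small enough for the naive viewshed oracle yet rich
enough to give every covariate in the model schema real variation:
ocean and beach on the east, a lake, forest, farmland, two wetland
types, an urban block with buildings, a monument knoll inside a park,
trails, and piers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon, box

from .dsm import PointCloud
from .grids import DEFAULT_CELLSIZE, ElevationGrid, GridSpec
from .regression import COVARIATE_SCHEMA, CovariateTable
from .vector_io import FeatureLayers

__all__ = [
    "SyntheticSpec",
    "Landscape",
    "DEFAULT_BETA_TRUE",
    "make_landscape",
    "make_photos",
    "make_counts",
    "surface_height",
    "scaled_scene",
    "beta_vector",
]

#: Placement/intensity coefficients of the default scene, on the
#: log-mean scale over the covariate schema.  Values follow the fitted
#: coastal-landscape pattern: strong positive ocean effect, negative
#: wetland/forest/agriculture effects, negative log-distance terms
#: (closer to coast/attractions = more views).
DEFAULT_BETA_TRUE: dict[str, float] = {
    "intercept": 1.8674,
    "forest": -0.8103,
    "agriculture": -0.5405,
    "fresh_water": -2.8201,
    "ocean": 2.2893,
    "woody_wetland": -1.2210,
    "emergent_wetland": -0.5918,
    "urban": 0.1780,
    "park": 0.5475,
    "trail": 0.2710,
    "logdist_coast": -0.6819,
    "logdist_lake": -0.1047,
    "logdist_attraction": -0.5665,
    "logdist_historical": -0.3236,
    "slope_deg": 0.0003,
    "pop_density": 0.0021,
}

DEFAULT_ALPHA_TRUE = 0.5  # moderate overdispersion


@dataclass(frozen=True)
class GaussianBump:
    cx: float
    cy: float
    height: float
    width: float  # Gaussian sigma, m


@dataclass(frozen=True)
class Wall:
    x1: float
    y1: float
    x2: float
    y2: float
    height: float


@dataclass
class SyntheticSpec:
    """Full description of a synthetic scene; defaults are the standard
    desk-scale coastal scene."""

    grid: GridSpec = field(
        default_factory=lambda: GridSpec(
            origin_x=0.0, origin_y=0.0, cellsize=DEFAULT_CELLSIZE,
            nrows=200, ncols=200,
        )
    )
    base_elevation: float = 2.0
    west_rise: float = 0.008  # m of elevation gain per m west of the coast
    bumps: tuple[GaussianBump, ...] = (
        GaussianBump(700.0, 700.0, 25.0, 60.0),  # monument knoll
    )
    walls: tuple[Wall, ...] = (
        Wall(480.0, 600.0, 480.0, 700.0, 8.0),  # planted occluder
    )
    coast_x: float = 975.0
    beach_min_x: float = 920.0
    dune_x: float = 947.0
    dune_height: float = 4.0
    dune_sigma: float = 18.0
    lake_center: tuple[float, float] = (280.0, 880.0)
    lake_radius: float = 90.0
    forest_box: tuple[float, float, float, float] = (0.0, 0.0, 420.0, 560.0)
    agriculture_box: tuple[float, float, float, float] = (0.0, 560.0, 420.0, 1219.2)
    woody_wetland_box: tuple[float, float, float, float] = (460.0, 760.0, 660.0, 1100.0)
    emergent_wetland_box: tuple[float, float, float, float] = (660.0, 760.0, 860.0, 1100.0)
    urban_box: tuple[float, float, float, float] = (560.0, 160.0, 860.0, 560.0)
    trail_x: float = 900.0
    trail_spur: tuple[tuple[float, float], tuple[float, float]] = (
        (900.0, 700.0), (700.0, 700.0)
    )
    park_boxes: tuple[tuple[float, float, float, float], ...] = (
        (600.0, 580.0, 820.0, 780.0),
        (880.0, 900.0, 975.0, 1219.2),
    )
    attraction_points: tuple[tuple[float, float], ...] = (
        (960.0, 400.0), (960.0, 800.0)
    )
    historical_points: tuple[tuple[float, float], ...] = ((700.0, 700.0),)
    pop_center: tuple[float, float] = (710.0, 360.0)
    pop_sigma: float = 150.0
    pop_peak: float = 800.0
    pop_base: float = 5.0
    canopy: Mapping[int, float] = field(
        default_factory=lambda: {42: 14.0, 90: 10.0, 95: 1.5}
    )
    building_density: float = 0.3
    building_height_range: tuple[float, float] = (4.0, 12.0)
    landcover_cell_factor: int = 5  # land-cover raster is this many times coarser
    points_per_cell: int = 4
    xy_jitter: bool = True
    z_noise_sd: float = 0.05
    n_noise_outliers: int = 20  # spuriously high returns, above the noise cap
    beta_true: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_TRUE)
    )
    alpha_true: float = DEFAULT_ALPHA_TRUE
    n_photos: int = 2000
    label_noise: float = 0.2  # symmetric flip probability per land-class tag
    nonrelevant_rate: float = 0.132
    seed: int = 20180322

    def __post_init__(self) -> None:
        if self.alpha_true <= 0:
            raise ValueError("alpha_true must be positive")
        if self.n_photos < 1:
            raise ValueError("n_photos must be >= 1")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")


# ---------------------------------------------------------------------------
# land cover zoning
# ---------------------------------------------------------------------------

def landcover_codes(spec: SyntheticSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Zone code at each (x, y): ocean 10, fresh water 11, urban 22,
    beach/barren 31, forest 42, grass 71, agriculture 82, wetlands 90/95.
    First matching zone wins."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    code = np.full(x.shape, 71, dtype=np.int64)  # grassland default

    def in_box(b):
        return (x >= b[0]) & (x < b[2]) & (y >= b[1]) & (y < b[3])

    lake = (x - spec.lake_center[0]) ** 2 + (y - spec.lake_center[1]) ** 2 <= (
        spec.lake_radius**2
    )
    zones = [
        (x >= spec.coast_x, 10),
        ((x >= spec.beach_min_x) & (x < spec.coast_x), 31),
        (lake, 11),
        (in_box(spec.woody_wetland_box), 90),
        (in_box(spec.emergent_wetland_box), 95),
        (in_box(spec.forest_box), 42),
        (in_box(spec.agriculture_box), 82),
        (in_box(spec.urban_box), 22),
    ]
    assigned = np.zeros(x.shape, dtype=bool)
    for mask, c in zones:
        take = mask & ~assigned
        code[take] = c
        assigned |= take
    return code


def _building_heights(spec: SyntheticSpec) -> np.ndarray:
    """Deterministic per-DSM-cell building heights inside the urban zone."""
    g = spec.grid
    rng = np.random.default_rng(spec.seed + 101)
    x, y = g.cell_centers()
    urban = landcover_codes(spec, x, y) == 22
    h = np.zeros(g.shape)
    present = rng.random(g.shape) < spec.building_density
    lo, hi = spec.building_height_range
    heights = rng.uniform(lo, hi, size=g.shape)
    h[urban & present] = heights[urban & present]
    return h


def surface_height(
    spec: SyntheticSpec,
    x: np.ndarray,
    y: np.ndarray,
    buildings: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic surface elevation (m) at arbitrary points.

    Base plane rising west of the coast + Gaussian bumps + zone canopy +
    buildings + planted walls; the ocean is forced to 0 m and the lake
    surface to 1 m.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    g = spec.grid
    code = landcover_codes(spec, x, y)
    z = spec.base_elevation + spec.west_rise * np.clip(spec.coast_x - x, 0.0, None)
    for b in spec.bumps:
        z = z + b.height * np.exp(
            -(((x - b.cx) ** 2) + ((y - b.cy) ** 2)) / (2.0 * b.width**2)
        )
    # dune ridge running the length of the beach
    ridge = spec.dune_height * np.exp(
        -((x - spec.dune_x) ** 2) / (2.0 * spec.dune_sigma**2)
    )
    z = z + np.where(code == 31, ridge, 0.0)
    for c, canopy_h in spec.canopy.items():
        z = z + np.where(code == c, canopy_h, 0.0)
    if buildings is None:
        buildings = _building_heights(spec)
    col = np.clip(
        np.floor((x - g.origin_x) / g.cellsize).astype(np.int64), 0, g.ncols - 1
    )
    row = np.clip(
        np.floor((y - g.origin_y) / g.cellsize).astype(np.int64), 0, g.nrows - 1
    )
    z = z + buildings[row, col]
    if spec.walls:
        pts = shapely.points(x.ravel(), y.ravel())
        for w in spec.walls:
            seg = LineString([(w.x1, w.y1), (w.x2, w.y2)])
            near = shapely.distance(pts, seg).reshape(x.shape) <= g.cellsize / 2.0
            z = z + np.where(near, w.height, 0.0)
    z = np.where(code == 10, 0.0, z)  # open sea
    z = np.where(code == 11, 1.0, z)  # lake surface
    return z


@dataclass
class Landscape:
    """Everything :func:`make_landscape` produces, plus the analytic
    truth grids used by tests."""

    spec: SyntheticSpec
    cloud: PointCloud
    landcover: ElevationGrid  # coarse categorical raster
    features: FeatureLayers
    population: ElevationGrid
    true_surface: ElevationGrid  # analytic surface at DSM resolution


def make_landscape(spec: SyntheticSpec) -> Landscape:
    """Generate the full input set: point cloud, land cover, vector
    layers and population raster, all co-registered and seeded."""
    g = spec.grid
    rng = np.random.default_rng(spec.seed)
    buildings = _building_heights(spec)

    # --- point cloud: jittered dense lattice on the analytic surface
    n_pts = g.nrows * g.ncols * spec.points_per_cell
    rows = np.repeat(np.arange(g.nrows), g.ncols * spec.points_per_cell)
    cols = np.tile(
        np.repeat(np.arange(g.ncols), spec.points_per_cell), g.nrows
    )
    if spec.xy_jitter:
        u = rng.random(n_pts)
        v = rng.random(n_pts)
    else:
        u = np.full(n_pts, 0.5)
        v = np.full(n_pts, 0.5)
    px = g.origin_x + (cols + u) * g.cellsize
    py = g.origin_y + (rows + v) * g.cellsize
    pz = surface_height(spec, px, py, buildings)
    if spec.z_noise_sd > 0:
        pz = pz + rng.normal(0.0, spec.z_noise_sd, n_pts)
    if spec.n_noise_outliers > 0:
        ox = g.origin_x + rng.random(spec.n_noise_outliers) * g.width
        oy = g.origin_y + rng.random(spec.n_noise_outliers) * g.height
        oz = rng.uniform(400.0, 900.0, spec.n_noise_outliers)
        px = np.concatenate([px, ox])
        py = np.concatenate([py, oy])
        pz = np.concatenate([pz, oz])
    cloud = PointCloud(px, py, pz)

    # --- land cover at a coarser resolution (NLCD-style)
    f = spec.landcover_cell_factor
    lc_spec = GridSpec(
        origin_x=g.origin_x, origin_y=g.origin_y,
        cellsize=g.cellsize * f,
        nrows=-(-g.nrows // f), ncols=-(-g.ncols // f),
    )
    lx, ly = lc_spec.cell_centers()
    landcover = ElevationGrid(
        lc_spec, landcover_codes(spec, lx, ly).astype(np.float64)
    )

    # --- vector layers
    lake_poly = Point(spec.lake_center).buffer(spec.lake_radius, quad_segs=32)
    features = FeatureLayers(
        coastline=[
            LineString([(spec.coast_x, g.origin_y), (spec.coast_x, g.origin_y + g.height)])
        ],
        lakes=[lake_poly],
        trails=[
            LineString([(spec.trail_x, g.origin_y), (spec.trail_x, g.origin_y + g.height)]),
            LineString(list(spec.trail_spur)),
        ],
        parks=[box(*b) for b in spec.park_boxes],
        attractions=[Point(p) for p in spec.attraction_points],
        historical=[Point(p) for p in spec.historical_points],
    )

    # --- population density: a blob over the urban core, per km^2
    xg, yg = g.cell_centers()
    pop = spec.pop_base + spec.pop_peak * np.exp(
        -(((xg - spec.pop_center[0]) ** 2) + ((yg - spec.pop_center[1]) ** 2))
        / (2.0 * spec.pop_sigma**2)
    )
    population = ElevationGrid(g, pop)

    true_surface = ElevationGrid(
        g, surface_height(spec, *g.cell_centers(), buildings)
    )
    return Landscape(spec, cloud, landcover, features, population, true_surface)


def make_counts(
    X: np.ndarray,
    beta_true: np.ndarray | Sequence[float],
    alpha_true: float,
    seed: int,
) -> np.ndarray:
    """Draw counts from NB2: mean exp(X beta), variance mu + alpha mu^2.

    Simulated as the exact gamma–Poisson mixture: lambda ~ Gamma(1/a,
    scale a mu), y ~ Poisson(lambda); easy to verify by moments.
    """
    if alpha_true <= 0:
        raise ValueError("alpha_true must be positive")
    rng = np.random.default_rng(seed)
    eta = np.clip(np.asarray(X, dtype=np.float64) @ np.asarray(beta_true), -30, 30)
    mu = np.exp(eta)
    lam = rng.gamma(shape=1.0 / alpha_true, scale=alpha_true * mu)
    return rng.poisson(lam).astype(np.int64)


def beta_vector(beta: Mapping[str, float]) -> np.ndarray:
    """Arrange a named coefficient mapping into model order
    (intercept first, then the covariate schema)."""
    return np.array(
        [beta.get("intercept", 0.0)] + [beta.get(c, 0.0) for c in COVARIATE_SCHEMA]
    )


def scaled_scene(factor: float, **overrides) -> SyntheticSpec:
    """A geometrically self-similar shrink of the default scene.

    All planimetric coordinates (zones, features, bump centres and
    widths) scale by ``factor``; heights and the cell size do not, so
    occlusion relationships stay meaningful.  Handy for fast tests:
    ``scaled_scene(0.3)`` is a 60x60 scene with every land-cover class
    still present.
    """
    if not (0 < factor <= 1):
        raise ValueError("factor must lie in (0, 1]")
    d = SyntheticSpec()
    g = d.grid

    def s(v):
        return v * factor

    def sbox(b):
        return tuple(s(v) for v in b)

    def spt(p):
        return (s(p[0]), s(p[1]))

    params = dict(
        grid=GridSpec(
            origin_x=g.origin_x, origin_y=g.origin_y, cellsize=g.cellsize,
            nrows=max(8, round(g.nrows * factor)),
            ncols=max(8, round(g.ncols * factor)),
        ),
        bumps=tuple(
            GaussianBump(s(b.cx), s(b.cy), b.height, s(b.width)) for b in d.bumps
        ),
        walls=tuple(
            Wall(s(w.x1), s(w.y1), s(w.x2), s(w.y2), w.height) for w in d.walls
        ),
        coast_x=s(d.coast_x),
        beach_min_x=s(d.beach_min_x),
        dune_x=s(d.dune_x),
        dune_sigma=max(d.grid.cellsize, s(d.dune_sigma)),
        lake_center=spt(d.lake_center),
        lake_radius=s(d.lake_radius),
        forest_box=sbox(d.forest_box),
        agriculture_box=sbox(d.agriculture_box),
        woody_wetland_box=sbox(d.woody_wetland_box),
        emergent_wetland_box=sbox(d.emergent_wetland_box),
        urban_box=sbox(d.urban_box),
        trail_x=s(d.trail_x),
        trail_spur=(spt(d.trail_spur[0]), spt(d.trail_spur[1])),
        park_boxes=tuple(sbox(b) for b in d.park_boxes),
        attraction_points=tuple(spt(p) for p in d.attraction_points),
        historical_points=tuple(spt(p) for p in d.historical_points),
        pop_center=spt(d.pop_center),
        pop_sigma=s(d.pop_sigma),
    )
    params.update(overrides)
    return SyntheticSpec(**params)


def make_photos(
    spec: SyntheticSpec,
    covariates: CovariateTable,
    dsm: ElevationGrid,
    landcover_fine: ElevationGrid,
    viewshed_fn=None,
):
    """Place photos and derive their (noisy) content labels.

    Placement: cells are drawn (with replacement — several photos may
    share a location, as real uploads do) with probability proportional
    to exp(x . beta_true) over the candidate cells in ``covariates``.
    Labels: each photo's land-class tags are read off its true viewshed
    composition, then each tag is flipped symmetrically with the
    configured noise probability; a configured fraction of photos is
    marked non-relevant with empty labels.

    Returns ``(photos, viewsheds_by_cell)`` where ``photos`` is a
    DataFrame (id, x, y, row, col, relevant, labels) and the dict maps
    each occupied cell to its ViewshedResult (reusable downstream).
    """
    import pandas as pd

    from .validation import DEFAULT_TAG_TO_CODES
    from .viewshed import ObserverSpec, viewshed

    if viewshed_fn is None:
        viewshed_fn = viewshed
    rng = np.random.default_rng(spec.seed + 202)
    bvec = beta_vector(spec.beta_true)
    X, _ = covariates.design_matrix()
    eta = X @ bvec
    w = np.exp(eta - eta.max())
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("all placement weights are zero or non-finite")
    pick = rng.choice(len(w), size=spec.n_photos, replace=True, p=w / total)
    rows = covariates.data["row"].to_numpy()[pick]
    cols = covariates.data["col"].to_numpy()[pick]
    g = dsm.spec
    # photos sit at their cell centres: sub-cell position is irrelevant
    # to a cell-snapped viewshed and keeps placement exactly reproducible
    xs = g.origin_x + (cols + 0.5) * g.cellsize
    ys = g.origin_y + (rows + 0.5) * g.cellsize

    vs_by_cell: dict[tuple[int, int], object] = {}
    tags = sorted(DEFAULT_TAG_TO_CODES)
    tag_codes = {
        t: set(DEFAULT_TAG_TO_CODES[t]) for t in tags
    }
    relevant = rng.random(spec.n_photos) >= spec.nonrelevant_rate
    labels: list[str] = []
    for i in range(spec.n_photos):
        cell = (int(rows[i]), int(cols[i]))
        if cell not in vs_by_cell:
            vs_by_cell[cell] = viewshed_fn(
                dsm, ObserverSpec(x=float(xs[i]), y=float(ys[i]))
            )
        if not relevant[i]:
            labels.append("")
            continue
        vs = vs_by_cell[cell]
        vals = landcover_fine.z[vs.mask]
        vals = set(vals[~np.isnan(vals)].astype(np.int64).tolist())
        photo_tags = []
        for t in tags:
            present = bool(vals & tag_codes[t])
            if rng.random() < spec.label_noise:
                present = not present
            if present:
                photo_tags.append(t)
        if rng.random() < 0.188:
            photo_tags.append("outdoor_activity")
        if rng.random() < 0.294:
            photo_tags.append("monument_attraction")
        if rng.random() < 0.131:
            photo_tags.append("plants_animals")
        if rng.random() < 0.130:
            photo_tags.append("sunset_weather")
        if not photo_tags:
            # a relevant photo with no recognisable land class still shows
            # *something*; a content-only tag keeps the record well formed
            # without entering the land-cover agreement comparison
            photo_tags = ["outdoor_activity"]
        labels.append(";".join(photo_tags))
    photos = pd.DataFrame(
        {
            "id": [f"p{i:05d}" for i in range(spec.n_photos)],
            "x": xs,
            "y": ys,
            "row": rows,
            "col": cols,
            "relevant": relevant,
            "labels": labels,
        }
    )
    return photos, vs_by_cell
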