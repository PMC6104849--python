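"""End-to-end orchestration: surface model -> viewsheds -> intensity ->
composition -> validation -> intensity model.

Every run writes its resolved configuration, a stage-by-stage manifest
(seeds, checksums, timings) and the conservation check
``sum(intensity) == sum(visible counts)``.  Stages are resumable: a
stage whose output file already exists is loaded instead of recomputed,
and recomputation is deterministic, so deleting any intermediate and
resuming reproduces it bit-exactly.

All inputs must share one projected CRS; grids that do not co-register
raise before any computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dsm import DEFAULT_Z_CAP, bin_points, slope_degrees
from .grids import ElevationGrid, read_ascii_grid, resample_nearest, write_ascii_grid
from .intensity import IntensityGrid, accumulate, composition, composition_summary
from .regression import build_covariates, fit_nb, morans_i, report, vif
from .synthetic import Landscape, SyntheticSpec, make_landscape, make_photos
from .validation import (
    LAND_CLASS_TAGS,
    PhotoLabelRecord,
    agreement_report,
    relevance_summary,
)
from .viewshed import (
    DEFAULT_EYE_HEIGHT,
    DEFAULT_MAX_RANGE,
    ObserverSpec,
    ViewshedResult,
    viewshed,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Parameters of a pipeline run.  Defaults are the study conditions:
    6.096 m cells, 300 m noise cap, 1.6 m eye height, 3 km view range,
    1% cell sample, 100 m trail buffer."""

    out_dir: str = "pipeline_out"
    z_cap: float = DEFAULT_Z_CAP
    eye_height: float = DEFAULT_EYE_HEIGHT
    max_range: float = DEFAULT_MAX_RANGE
    sample_fraction: float = 0.01
    trail_buffer_m: float = 100.0
    sample_seed: int = 42
    scene: SyntheticSpec = field(default_factory=SyntheticSpec)

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2,
                          sort_keys=True)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run (or resume) the full pipeline on the configured synthetic
    scene; returns the manifest dict (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    manifest: dict = {
        "version": __version__,
        "stages": {},
        "seeds": {"scene": config.scene.seed, "sample": config.sample_seed},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **info
            }

        return done

    # --- scene ------------------------------------------------------------
    fin = stage("scene")
    scene = config.scene
    land: Landscape = make_landscape(scene)
    fin(n_points=len(land.cloud), seed=scene.seed)

    # --- surface model ----------------------------------------------------
    fin = stage("dsm")
    dsm_path = out / "dsm.asc"
    if dsm_path.exists():
        dsm = read_ascii_grid(dsm_path)
        cached = True
    else:
        dsm = bin_points(land.cloud, scene.grid, config.z_cap)
        write_ascii_grid(dsm, dsm_path)
        cached = False
    fin(cached=cached, checksum=_checksum(dsm.z), nodata_cells=int(dsm.nodata_mask.sum()))

    fin = stage("slope")
    slope_path = out / "slope.asc"
    if slope_path.exists():
        slope = read_ascii_grid(slope_path)
        cached = True
    else:
        slope = slope_degrees(dsm)
        write_ascii_grid(slope, slope_path)
        cached = False
    fin(cached=cached, checksum=_checksum(slope.z))

    # --- co-registration checks ------------------------------------------
    if not land.population.spec.same_geometry(dsm.spec):
        raise ValueError("population raster does not co-register with the DSM")
    landcover_fine = resample_nearest(land.landcover, dsm.spec)

    # --- photo placement (needs the full covariate grid) ------------------
    fin = stage("photos")
    zero_intensity = IntensityGrid(dsm.spec, np.zeros(dsm.spec.shape, dtype=np.int64))
    full_cov = build_covariates(
        zero_intensity, landcover_fine, slope, land.population,
        land.features.coastline, land.features.lakes, land.features.trails,
        land.features.parks, land.features.attractions, land.features.historical,
        fraction=1.0, seed=scene.seed,
        trail_buffer_m=config.trail_buffer_m,
    )
    photos_path = out / "photos.csv"
    vs_by_cell: dict[tuple[int, int], ViewshedResult] = {}
    if photos_path.exists():
        photos = pd.read_csv(photos_path, keep_default_na=False)
        cached = True
    else:
        photos, vs_by_cell = make_photos(scene, full_cov, dsm, landcover_fine)
        photos.to_csv(photos_path, index=False)
        cached = False
    fin(cached=cached, n_photos=len(photos),
        n_relevant=int(photos["relevant"].sum()))

    # --- per-photo viewsheds and the intensity overlay --------------------
    fin = stage("intensity")
    cells = list(zip(photos["row"].astype(int), photos["col"].astype(int)))
    for (r, c) in sorted(set(cells)):
        if (r, c) not in vs_by_cell:
            x, y = dsm.spec.center_of(r, c)
            vs_by_cell[(r, c)] = viewshed(
                dsm, ObserverSpec(x, y, config.eye_height, config.max_range)
            )
    photo_viewsheds = [vs_by_cell[rc] for rc in cells]
    total_visible = sum(vs.visible_count for vs in photo_viewsheds)
    intensity_path = out / "intensity.asc"
    if intensity_path.exists():
        ig = read_ascii_grid(intensity_path)
        intens = IntensityGrid(ig.spec, ig.z.astype(np.int64))
        cached = True
    else:
        intens = accumulate(photo_viewsheds, dsm.spec, ids=photos["id"].tolist())
        write_ascii_grid(
            ElevationGrid(dsm.spec, intens.counts.astype(np.float64)),
            intensity_path,
        )
        cached = False
    conserved = int(intens.counts.sum()) == total_visible
    if not conserved:
        raise RuntimeError(
            f"conservation check failed: sum(intensity)={intens.counts.sum()} "
            f"!= sum(visible counts)={total_visible}"
        )
    fin(cached=cached, total_intensity=int(intens.counts.sum()),
        total_visible=total_visible, conservation_ok=conserved)

    # --- land-cover composition ------------------------------------------
    fin = stage("composition")
    comp_path = out / "composition_summary.csv"
    records = [
        composition(vs_by_cell[rc], landcover_fine, photo_id=pid)
        for rc, pid in zip(cells, photos["id"])
    ]
    comp = composition_summary(records)
    if not comp_path.exists():
        comp.to_csv(comp_path, index=False)
    fin(cached=False, n_records=len(records))

    # --- content validation ----------------------------------------------
    fin = stage("validation")
    label_records = [
        PhotoLabelRecord(
            photo_id=row.id,
            labels=frozenset(str(row.labels).split(";")) - {""},
            relevant=bool(row.relevant),
        )
        for row in photos.itertuples()
    ]
    vs_by_id = {pid: vs_by_cell[rc] for pid, rc in zip(photos["id"], cells)}
    agreement = agreement_report(label_records, vs_by_id, landcover_fine)
    relevance = relevance_summary(label_records)
    validation = {
        "relevance": relevance,
        "agreement": [
            {
                "class": a.class_tag,
                "table": list(a.table),
                "percent_agreement": a.percent_agreement,
                "kappa": a.kappa,
            }
            for a in agreement
        ],
    }
    (out / "validation.json").write_text(json.dumps(validation, indent=2))
    fin(n_classes=len(agreement))

    # --- intensity model --------------------------------------------------
    fin = stage("model")
    table = build_covariates(
        intens, landcover_fine, slope, land.population,
        land.features.coastline, land.features.lakes, land.features.trails,
        land.features.parks, land.features.attractions, land.features.historical,
        fraction=config.sample_fraction, seed=config.sample_seed,
        trail_buffer_m=config.trail_buffer_m,
    )
    table.to_csv(out / "covariates.csv")
    X, names = table.design_matrix()
    vif_table = vif(X[:, 1:], names=names[1:])
    fit = fit_nb(table)
    model_df = report(fit, table)
    mu = fit.predict_mu(X)
    pearson = (table.y - mu) / np.sqrt(mu + fit.alpha * mu**2)
    coords = np.column_stack([table.data["col"], table.data["row"]]).astype(float)
    mi, mi_p = morans_i(pearson, coords, seed=config.sample_seed)
    model_report = {
        "alpha": fit.alpha,
        "aic": fit.aic,
        "loglik": fit.loglik,
        "r2_mcfadden": fit.r2_mcfadden,
        "r2_nagelkerke": fit.r2_nagelkerke,
        "morans_i": mi,
        "morans_i_p": mi_p,
        "n_obs": fit.n_obs,
        "terms": model_df.to_dict(orient="records"),
        "vif": vif_table.to_dict(orient="records"),
    }
    (out / "model_report.json").write_text(json.dumps(model_report, indent=2))
    fin(alpha=fit.alpha, aic=fit.aic, n_obs=fit.n_obs)

    manifest["conservation_ok"] = conserved
    manifest["checksums"] = {
        "dsm": _checksum(dsm.z),
        "intensity": _checksum(intens.counts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
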