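"""Cumulative viewshed ("viewshed intensity") and land-cover composition.

Overlaying all per-photo viewsheds gives, per cell, the number of photo
locations from which that cell is visible — the intensity surface that
the count regression models.  Composition summarises which land-cover
classes are visible from each photo location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import ElevationGrid, GridSpec
from .viewshed import ViewshedResult

__all__ = [
    "IntensityGrid",
    "CompositionRecord",
    "accumulate",
    "composition",
    "composition_summary",
]


@dataclass
class IntensityGrid:
    spec: GridSpec
    counts: np.ndarray = field(repr=False)  # int64, overlapping viewsheds per cell

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.spec.shape:
            raise ValueError("counts shape does not match grid spec")
        if (self.counts < 0).any():
            raise ValueError("intensity counts must be non-negative")


@dataclass
class CompositionRecord:
    photo_id: str
    class_fractions: dict[int, float]


def accumulate(
    viewsheds: Iterable[ViewshedResult],
    spec: GridSpec,
    ids: Sequence | None = None,
) -> IntensityGrid:
    """Per-cell count of overlapping viewshed masks (order-invariant).

    Conservation holds by construction: the grand total equals the sum
    of the individual visible counts.
    """
    counts = np.zeros(spec.shape, dtype=np.int64)
    for i, vs in enumerate(viewsheds):
        if vs.mask.shape != spec.shape:
            pid = ids[i] if ids is not None else i
            raise ValueError(
                f"viewshed {pid!r} mask shape {vs.mask.shape} is misaligned "
                f"with the target grid {spec.shape}"
            )
        counts += vs.mask
    return IntensityGrid(spec, counts)


def composition(
    vs: ViewshedResult,
    landcover: ElevationGrid,
    photo_id: str = "",
) -> CompositionRecord:
    """Fraction of each land-cover class among visible non-nodata cells.

    ``landcover`` must already be aligned to the viewshed grid (use
    :func:`viewscape.grids.resample_nearest` for coarser products).
    """
    if vs.mask.shape != landcover.spec.shape:
        raise ValueError("land-cover raster is misaligned with the viewshed mask")
    vals = landcover.z[vs.mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(
            f"viewshed {photo_id!r} has no visible cell with land-cover data"
        )
    codes, counts = np.unique(vals.astype(np.int64), return_counts=True)
    total = counts.sum()
    return CompositionRecord(
        photo_id=photo_id,
        class_fractions={int(c): float(n) / total for c, n in zip(codes, counts)},
    )


def composition_summary(
    records: Sequence[CompositionRecord],
    population_sd: bool = False,
    class_names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Per-class mean percentage and standard deviation across viewsheds.

    A class absent from a viewshed contributes 0% to that viewshed's
    entry.  The default SD is the sample SD (ddof=1); with one record it
    is reported as 0 by convention.
    """
    if len(records) == 0:
        raise ValueError("composition_summary requires at least one record")
    all_codes = sorted({c for r in records for c in r.class_fractions})
    mat = np.zeros((len(records), len(all_codes)))
    for i, r in enumerate(records):
        for j, code in enumerate(all_codes):
            mat[i, j] = r.class_fractions.get(code, 0.0)
    pct = mat * 100.0
    mean = pct.mean(axis=0)
    if len(records) == 1:
        sd = np.zeros(len(all_codes))
    else:
        sd = pct.std(axis=0, ddof=0 if population_sd else 1)
    df = pd.DataFrame(
        {"class_code": all_codes, "mean_pct": mean, "sd_pct": sd}
    ).sort_values("mean_pct", ascending=False, kind="stable").reset_index(drop=True)
    if class_names:
        df.insert(1, "class_name", [class_names.get(c, str(c)) for c in df.class_code])
    return df
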