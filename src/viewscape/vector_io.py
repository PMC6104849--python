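"""GeoJSON reading/writing for the vector feature layers.

All layers live in one projected CRS (metres); geometries are plain
shapely objects.  A feature collection round-trips through
:func:`write_geojson` / :func:`read_geojson` losslessly at full float
precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

from shapely.geometry import mapping, shape

__all__ = ["read_geojson", "write_geojson", "FeatureLayers"]


def read_geojson(path: str | Path) -> list:
    """Read a GeoJSON file into a list of shapely geometries."""
    doc = json.loads(Path(path).read_text())
    t = doc.get("type")
    if t == "FeatureCollection":
        return [shape(f["geometry"]) for f in doc["features"]]
    if t == "Feature":
        return [shape(doc["geometry"])]
    return [shape(doc)]


def write_geojson(geoms: Sequence, path: str | Path) -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {}, "geometry": mapping(g)}
            for g in geoms
        ],
    }
    Path(path).write_text(json.dumps(doc))


@dataclass
class FeatureLayers:
    """The vector layers the intensity model draws covariates from."""

    coastline: list  # LineStrings along the land/sea edge
    lakes: list  # lake & river polygons (fresh water)
    trails: list  # walking/cycling path LineStrings
    parks: list  # protected-area polygons
    attractions: list  # coastal attraction Points (piers, rentals...)
    historical: list  # historical attraction Points (monuments...)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for f in fields(self):
            write_geojson(getattr(self, f.name), out_dir / f"{f.name}.geojson")

    @classmethod
    def load(cls, in_dir: str | Path) -> "FeatureLayers":
        in_dir = Path(in_dir)
        return cls(
            **{
                f.name: read_geojson(in_dir / f"{f.name}.geojson")
                for f in fields(cls)
            }
        )
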