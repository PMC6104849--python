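"""Digital surface model construction from point clouds.

The surface model is built by *max-Z binning*: each grid cell takes the
maximum return elevation among the points that fall in it, after
discarding returns above a noise cap (spuriously high returns — birds,
multipath — are deleted, not clamped).  Cells that receive no surviving
point are nodata.

Terrain slope is derived with Horn's 3x3 finite-difference operator, the
standard in raster GIS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import ElevationGrid, GridSpec

__all__ = [
    "PointCloud",
    "NonFiniteRecordWarning",
    "read_xyz",
    "write_xyz",
    "bin_points",
    "slope_degrees",
    "fill_nodata",
]

#: Default noise cap in metres: returns above this are treated as outliers.
DEFAULT_Z_CAP = 300.0


class NonFiniteRecordWarning(UserWarning):
    """Raised (as a warning) when cloud records with non-finite coordinates
    are rejected; carries the rejected count."""

    def __init__(self, count: int):
        self.count = count
        super().__init__(f"rejected {count} point(s) with non-finite coordinates")


@dataclass
class PointCloud:
    """Columnar x/y/z arrays of survey returns, coordinates in metres."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=np.float64))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=np.float64))
        self.z = np.atleast_1d(np.asarray(self.z, dtype=np.float64))
        if not (self.x.shape == self.y.shape == self.z.shape):
            raise ValueError("x, y, z must have equal length")

    def __len__(self) -> int:
        return self.x.size

    @classmethod
    def from_records(cls, records) -> "PointCloud":
        arr = np.asarray(list(records), dtype=np.float64)
        if arr.size == 0:
            return cls(np.empty(0), np.empty(0), np.empty(0))
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])


def read_xyz(path: str | Path) -> PointCloud:
    """Read a whitespace- or comma-delimited x y z text file.

    Binary survey formats (LAS/LAZ) are not supported; convert to XYZ
    text first.
    """
    path = Path(path)
    if path.suffix.lower() in {".las", ".laz"}:
        raise ValueError(
            f"{path.name}: LAS/LAZ is not supported; supply whitespace or "
            "comma-delimited XYZ text"
        )
    try:
        arr = np.loadtxt(path, ndmin=2)
    except ValueError:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if arr.size == 0:
        return PointCloud(np.empty(0), np.empty(0), np.empty(0))
    if arr.shape[1] < 3:
        raise ValueError(f"{path.name}: expected at least 3 columns (x y z)")
    return PointCloud(arr[:, 0], arr[:, 1], arr[:, 2])


def write_xyz(cloud: PointCloud, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([cloud.x, cloud.y, cloud.z]), fmt="%.17g")


def bin_points(
    cloud: PointCloud, spec: GridSpec, z_cap: float = DEFAULT_Z_CAP
) -> ElevationGrid:
    """Max-Z bin a point cloud onto a grid.

    Points with ``z > z_cap`` are discarded before the per-cell maximum,
    as are points outside the grid extent.  Non-finite records are
    rejected with a :class:`NonFiniteRecordWarning` carrying the count.
    Cells with no surviving point hold nodata.
    """
    if z_cap <= 0:
        raise ValueError(f"z_cap must be positive, got {z_cap}")
    x, y, z = cloud.x, cloud.y, cloud.z
    finite = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    n_bad = int((~finite).sum())
    if n_bad:
        warnings.warn(NonFiniteRecordWarning(n_bad), stacklevel=2)
        x, y, z = x[finite], y[finite], z[finite]
    keep = z <= z_cap
    x, y, z = x[keep], y[keep], z[keep]
    col = np.floor((x - spec.origin_x) / spec.cellsize).astype(np.int64)
    row = np.floor((y - spec.origin_y) / spec.cellsize).astype(np.int64)
    inside = (row >= 0) & (row < spec.nrows) & (col >= 0) & (col < spec.ncols)
    row, col, z = row[inside], col[inside], z[inside]
    out = np.full(spec.shape, -np.inf)
    np.maximum.at(out, (row, col), z)
    out[np.isinf(out)] = np.nan
    return ElevationGrid(spec, out)


def slope_degrees(dem: ElevationGrid) -> ElevationGrid:
    """Horn 3x3 slope in degrees, border cells by edge replication.

    Any window touching a nodata cell yields nodata (nodata propagates).
    """
    if dem.spec.nrows < 3 or dem.spec.ncols < 3:
        raise ValueError("slope requires a grid of at least 3x3 cells")
    h = dem.spec.cellsize
    z = np.pad(dem.z, 1, mode="edge")
    # neighbours named by compass direction; internal row 0 is south
    sw, s, se = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w, e = z[1:-1, :-2], z[1:-1, 2:]
    nw, n, ne = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8 * h)
    dzdy = ((ne + 2 * n + nw) - (se + 2 * s + sw)) / (8 * h)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    bad = ndimage.maximum_filter(np.isnan(dem.z).astype(np.int8), size=3, mode="nearest")
    slope[bad > 0] = np.nan
    return ElevationGrid(dem.spec, slope)


def fill_nodata(grid: ElevationGrid, policy: str = "none") -> ElevationGrid:
    """Fill nodata cells.

    policy "none" returns the input unchanged; "nearest" assigns each
    nodata cell the value of its nearest (cell-centre Euclidean)
    non-nodata cell, ties broken by smaller row then smaller column.
    """
    if policy not in {"none", "nearest"}:
        raise ValueError(f"unknown fill policy {policy!r}; use 'none' or 'nearest'")
    if policy == "none":
        return grid
    mask = grid.nodata_mask
    if mask.all():
        raise ValueError("cannot fill an all-nodata grid with policy 'nearest'")
    if not mask.any():
        return grid.copy()
    from scipy.spatial import cKDTree

    src_rc = np.argwhere(~mask)
    tree = cKDTree(src_rc.astype(np.float64))
    tgt_rc = np.argwhere(mask)
    k = min(16, len(src_rc))
    dist, idx = tree.query(tgt_rc.astype(np.float64), k=k)
    dist = np.atleast_2d(dist.reshape(len(tgt_rc), -1))
    idx = np.atleast_2d(idx.reshape(len(tgt_rc), -1))
    out = grid.z.copy()
    for t in range(len(tgt_rc)):
        d0 = dist[t, 0]
        tied = np.flatnonzero(dist[t] <= d0 + 1e-9)
        if len(tied) == k and k < len(src_rc):
            # tie set may extend beyond k neighbours: fall back to full search
            dd = np.sum((src_rc - tgt_rc[t]) ** 2, axis=1)
            cand = src_rc[dd <= dd.min() + 1e-9]
        else:
            cand = src_rc[idx[t, tied]]
        order = np.lexsort((cand[:, 1], cand[:, 0]))
        r, c = cand[order[0]]
        out[tuple(tgt_rc[t])] = grid.z[r, c]
    return ElevationGrid(grid.spec, out)
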