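"""Georeferenced raster grids and their plain-text serialisation.

All grids in this package share one convention: the origin is the
lower-left corner of the raster, row 0 is the SOUTHERNMOST row, and a
point belongs to cell ``(floor((y - y0)/h), floor((x - x0)/h))`` —
half-open intervals, so a point on a shared edge falls in the cell with
the larger index.  Writers translate to the top-down row order that the
ESRI ASCII grid format expects.

Missing cells are represented internally as NaN; the ``nodata`` sentinel
in :class:`GridSpec` only matters at the file boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "ElevationGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "resample_nearest",
]

#: Default cell size in metres (20 ft), the resolution of the surface model.
DEFAULT_CELLSIZE = 6.096

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: lower-left origin, square cells, row 0 south."""

    origin_x: float
    origin_y: float
    cellsize: float = DEFAULT_CELLSIZE
    nrows: int = 1
    ncols: int = 1
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        # coerce numpy scalars so headers serialise as plain numbers
        for f, typ in (("origin_x", float), ("origin_y", float),
                       ("cellsize", float), ("nrows", int), ("ncols", int),
                       ("nodata", float)):
            object.__setattr__(self, f, typ(getattr(self, f)))
        if self.cellsize <= 0:
            raise ValueError(f"cellsize must be positive, got {self.cellsize}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def width(self) -> float:
        return self.ncols * self.cellsize

    @property
    def height(self) -> float:
        return self.nrows * self.cellsize

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Containing cell of a point; raises if outside the extent."""
        col = math.floor((x - self.origin_x) / self.cellsize)
        row = math.floor((y - self.origin_y) / self.cellsize)
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(
                f"point ({x}, {y}) lies outside the grid extent "
                f"[{self.origin_x}, {self.origin_x + self.width}) x "
                f"[{self.origin_y}, {self.origin_y + self.height})"
            )
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cellsize,
            self.origin_y + (row + 0.5) * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre, shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.origin_x + (cols + 0.5) * self.cellsize
        y = self.origin_y + (rows + 0.5) * self.cellsize
        return np.broadcast_to(x, (self.nrows, self.ncols)).copy(), np.broadcast_to(
            y[:, None], (self.nrows, self.ncols)
        ).copy()

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, abs_tol=1e-6)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=1e-6)
            and math.isclose(self.cellsize, other.cellsize, rel_tol=1e-12)
        )


@dataclass
class ElevationGrid:
    """A raster of values (surface heights, counts, class codes...).

    ``z`` is float64 with NaN for nodata, shape ``spec.shape``.
    """

    spec: GridSpec
    z: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.shape != self.spec.shape:
            raise ValueError(
                f"array shape {self.z.shape} does not match spec {self.spec.shape}"
            )

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.z)

    def copy(self) -> "ElevationGrid":
        return ElevationGrid(self.spec, self.z.copy())


def write_ascii_grid(grid: ElevationGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid.  Values use repr precision (%.17g) so a
    read-back reproduces every float bit-exactly."""
    spec = grid.spec
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {spec.ncols}\n")
        fh.write(f"nrows {spec.nrows}\n")
        fh.write(f"xllcorner {spec.origin_x!r}\n")
        fh.write(f"yllcorner {spec.origin_y!r}\n")
        fh.write(f"cellsize {spec.cellsize!r}\n")
        fh.write(f"NODATA_value {spec.nodata!r}\n")
        data = np.where(np.isnan(grid.z), spec.nodata, grid.z)
        # file rows run north->south; internal row 0 is the southernmost
        for r in range(spec.nrows - 1, -1, -1):
            fh.write(" ".join(f"{v:.17g}" for v in data[r]) + "\n")


def read_ascii_grid(path: str | Path) -> ElevationGrid:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=np.float64))
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid {path} missing header field {req!r}")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    spec = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cellsize=header["cellsize"],
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        nodata=nodata,
    )
    data = np.vstack(rows)
    if data.shape != spec.shape:
        raise ValueError(
            f"ASCII grid {path}: data shape {data.shape} does not match header "
            f"{spec.shape}"
        )
    data = data[::-1].copy()  # back to row 0 = south
    z = np.where(data == nodata, np.nan, data)
    return ElevationGrid(spec, z)


def resample_nearest(src: ElevationGrid, dst_spec: GridSpec) -> ElevationGrid:
    """Nearest-neighbour resample of ``src`` onto ``dst_spec``'s geometry.

    Used to bring a coarser categorical layer (e.g. a 30 m land-cover
    product) onto the surface-model grid; categorical codes must never be
    averaged.  Destination cells whose centres fall outside the source
    extent become nodata.
    """
    if src.spec.same_geometry(dst_spec):
        return ElevationGrid(replace(src.spec, nodata=dst_spec.nodata), src.z.copy())
    x, y = dst_spec.cell_centers()
    col = np.floor((x - src.spec.origin_x) / src.spec.cellsize).astype(np.int64)
    row = np.floor((y - src.spec.origin_y) / src.spec.cellsize).astype(np.int64)
    inside = (
        (row >= 0) & (row < src.spec.nrows) & (col >= 0) & (col < src.spec.ncols)
    )
    out = np.full(dst_spec.shape, np.nan)
    out[inside] = src.z[row[inside], col[inside]]
    return ElevationGrid(dst_spec, out)
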