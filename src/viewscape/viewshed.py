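"""Line-of-sight and viewshed computation on a surface model.

Reference semantics (normative for this package, and shared bit-for-bit
by the fast kernel and the naive oracle):

* The observer stands ON the surface model — canopy and buildings
  included — at ``dsm(observer cell) + eye_height``.
* A target cell is considered at its surface elevation, centre to
  centre, within an inclusive ``max_range`` (Euclidean, projected m).
* The sight line is sampled every ``cellsize/2`` along the segment
  between the two cell centres; samples falling inside the observer or
  target cell are excluded; terrain at a sample is the value of the
  containing cell (nearest-cell lookup).
* The target is visible iff the maximum sample tangent
  ``(z_s - z_o)/d_s`` does not exceed the target tangent
  ``(z_t - z_o)/d_t``.  Ties count as visible (grazing rays pass).
* Nodata samples neither occlude nor are visible as targets.

Earth curvature and refraction are ignored: at the 3 km default range
the curvature drop (~0.7 m) is below the surface-model noise floor.

``viewshed`` runs a compiled kernel; ``viewshed_naive`` is an
independent, plain-Python implementation of the same semantics used as
a testing oracle.  They must agree exactly on every cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .grids import ElevationGrid

__all__ = [
    "ObserverSpec",
    "ViewshedResult",
    "line_of_sight",
    "viewshed",
    "viewshed_naive",
]

DEFAULT_EYE_HEIGHT = 1.6  # m, assumed human eye level
DEFAULT_MAX_RANGE = 3000.0  # m


@dataclass(frozen=True)
class ObserverSpec:
    """A photo location: position in projected metres, eye height, range."""

    x: float
    y: float
    eye_height: float = DEFAULT_EYE_HEIGHT
    max_range: float = DEFAULT_MAX_RANGE

    def __post_init__(self) -> None:
        if self.eye_height <= 0:
            raise ValueError("eye_height must be positive")
        if self.max_range <= 0:
            raise ValueError("max_range must be positive")


@dataclass
class ViewshedResult:
    observer_cell: tuple[int, int]
    mask: np.ndarray = field(repr=False)  # bool, aligned to the DSM grid
    visible_count: int = 0
    visible_area: float = 0.0


def _observer_state(dsm: ElevationGrid, obs: ObserverSpec) -> tuple[int, int, float]:
    r0, c0 = dsm.spec.cell_of(obs.x, obs.y)  # raises outside extent
    z0 = dsm.z[r0, c0]
    if np.isnan(z0):
        raise ValueError(
            f"observer at ({obs.x}, {obs.y}) falls on a nodata cell "
            f"({r0}, {c0}); fill the surface model first (fill_nodata)"
        )
    return r0, c0, float(z0) + obs.eye_height


def line_of_sight(
    dsm: ElevationGrid, obs: ObserverSpec, target_cell: tuple[int, int]
) -> bool:
    """Is ``target_cell`` visible from the observer?  Reference semantics.

    The target must lie within ``max_range`` of the observer cell
    (centre-to-centre, inclusive).
    """
    r0, c0, z_o = _observer_state(dsm, obs)
    rt, ct = target_cell
    spec = dsm.spec
    h = spec.cellsize
    ox = spec.origin_x + (c0 + 0.5) * h
    oy = spec.origin_y + (r0 + 0.5) * h
    tx = spec.origin_x + (ct + 0.5) * h
    ty = spec.origin_y + (rt + 0.5) * h
    dx = tx - ox
    dy = ty - oy
    d_t = math.sqrt(dx * dx + dy * dy)
    if d_t > obs.max_range:
        raise ValueError(
            f"target {target_cell} at distance {d_t:.1f} m exceeds "
            f"max_range {obs.max_range} m"
        )
    if rt == r0 and ct == c0:
        return True
    zt = dsm.z[rt, ct]
    if math.isnan(zt):
        return False
    target_tan = (float(zt) - z_o) / d_t
    step = h / 2.0
    x0 = spec.origin_x
    y0 = spec.origin_y
    z = dsm.z
    max_tan = -math.inf
    k = 1
    s = step
    while s < d_t:
        frac = s / d_t
        px = ox + dx * frac
        py = oy + dy * frac
        cr = int(math.floor((py - y0) / h))
        cc = int(math.floor((px - x0) / h))
        if not ((cr == r0 and cc == c0) or (cr == rt and cc == ct)):
            zs = z[cr, cc]
            if not math.isnan(zs):
                tan_s = (zs - z_o) / s
                if tan_s > max_tan:
                    max_tan = tan_s
        k += 1
        s = k * step
    return max_tan <= target_tan


@njit(cache=False)
def _viewshed_kernel(z, x0, y0, h, r0, c0, z_o, max_range):  # pragma: no cover
    nrows, ncols = z.shape
    mask = np.zeros((nrows, ncols), dtype=np.uint8)
    ox = x0 + (c0 + 0.5) * h
    oy = y0 + (r0 + 0.5) * h
    step = h / 2.0
    for rt in range(nrows):
        for ct in range(ncols):
            tx = x0 + (ct + 0.5) * h
            ty = y0 + (rt + 0.5) * h
            dx = tx - ox
            dy = ty - oy
            d_t = math.sqrt(dx * dx + dy * dy)
            if d_t > max_range:
                continue
            if rt == r0 and ct == c0:
                mask[rt, ct] = 1
                continue
            zt = z[rt, ct]
            if math.isnan(zt):
                continue
            target_tan = (zt - z_o) / d_t
            max_tan = -math.inf
            k = 1
            s = step
            while s < d_t:
                frac = s / d_t
                px = ox + dx * frac
                py = oy + dy * frac
                cr = int(math.floor((py - y0) / h))
                cc = int(math.floor((px - x0) / h))
                if not ((cr == r0 and cc == c0) or (cr == rt and cc == ct)):
                    zs = z[cr, cc]
                    if not math.isnan(zs):
                        tan_s = (zs - z_o) / s
                        if tan_s > max_tan:
                            max_tan = tan_s
                k += 1
                s = k * step
            if max_tan <= target_tan:
                mask[rt, ct] = 1
    return mask


def viewshed(dsm: ElevationGrid, obs: ObserverSpec) -> ViewshedResult:
    """Visibility mask for one observer, via the compiled kernel."""
    r0, c0, z_o = _observer_state(dsm, obs)
    spec = dsm.spec
    mask = _viewshed_kernel(
        dsm.z, spec.origin_x, spec.origin_y, spec.cellsize, r0, c0, z_o,
        obs.max_range,
    ).astype(bool)
    count = int(mask.sum())
    return ViewshedResult(
        observer_cell=(r0, c0),
        mask=mask,
        visible_count=count,
        visible_area=count * spec.cellsize**2,
    )


def viewshed_naive(dsm: ElevationGrid, obs: ObserverSpec) -> ViewshedResult:
    """Straightforward per-target recomputation via :func:`line_of_sight`.

    Intended for small grids (<= 256x256 advisory); must agree exactly
    with :func:`viewshed` everywhere.
    """
    r0, c0, _ = _observer_state(dsm, obs)
    spec = dsm.spec
    h = spec.cellsize
    ox = spec.origin_x + (c0 + 0.5) * h
    oy = spec.origin_y + (r0 + 0.5) * h
    mask = np.zeros(spec.shape, dtype=bool)
    for rt in range(spec.nrows):
        ty = spec.origin_y + (rt + 0.5) * h
        for ct in range(spec.ncols):
            tx = spec.origin_x + (ct + 0.5) * h
            dxx = tx - ox
            dyy = ty - oy
            if math.sqrt(dxx * dxx + dyy * dyy) > obs.max_range:
                continue
            mask[rt, ct] = line_of_sight(dsm, obs, (rt, ct))
    count = int(mask.sum())
    return ViewshedResult(
        observer_cell=(r0, c0),
        mask=mask,
        visible_count=count,
        visible_area=count * spec.cellsize**2,
    )
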