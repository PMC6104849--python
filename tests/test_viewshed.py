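import math

import numpy as np
import pytest

from viewscape.grids import ElevationGrid, GridSpec
from viewscape.viewshed import (
    ObserverSpec,
    line_of_sight,
    viewshed,
    viewshed_naive,
)

from conftest import smooth_random_terrain


def dense_los_margin(dsm, obs, target, div=8):
    """Independent dense-sampling oracle (cellsize/div steps, same
    nearest-cell lookup).  Returns (visible, tangent margin)."""
    spec = dsm.spec
    h = spec.cellsize
    r0, c0 = spec.cell_of(obs.x, obs.y)
    z_o = dsm.z[r0, c0] + obs.eye_height
    rt, ct = target
    ox, oy = spec.center_of(r0, c0)
    tx, ty = spec.center_of(rt, ct)
    dx, dy = tx - ox, ty - oy
    d_t = math.sqrt(dx * dx + dy * dy)
    if (rt, ct) == (r0, c0):
        return True, math.inf
    zt = dsm.z[rt, ct]
    if math.isnan(zt):
        return False, math.inf
    target_tan = (zt - z_o) / d_t
    step = h / div
    max_tan = -math.inf
    k = 1
    while k * step < d_t:
        s = k * step
        frac = s / d_t
        cr = math.floor((oy + dy * frac - spec.origin_y) / h)
        cc = math.floor((ox + dx * frac - spec.origin_x) / h)
        if not ((cr == r0 and cc == c0) or (cr == rt and cc == ct)):
            zs = dsm.z[cr, cc]
            if not math.isnan(zs):
                max_tan = max(max_tan, (zs - z_o) / s)
        k += 1
    return max_tan <= target_tan, target_tan - max_tan


class TestLineOfSight:
    def test_flat_terrain_everything_in_range_visible(self, flat_grid):
        obs = ObserverSpec(20.5, 20.5, 1.6, 15.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            r, c = rng.integers(10, 31, 2)
            if math.hypot(r - 20, c - 20) <= 15.0:
                assert line_of_sight(flat_grid, obs, (int(r), int(c)))

    def test_wall_blocks_ground_target_by_tangent_arithmetic(self):
        # cells of 10 m; observer col 2, 10 m wall at 100 m, target at 200 m
        spec = GridSpec(0.0, 0.0, 10.0, 3, 41)
        z = np.zeros((3, 41))
        z[1, 12] = 10.0
        g = ElevationGrid(spec, z)
        obs = ObserverSpec(25.0, 15.0, 1.6, 3000.0)
        # wall tangent (10-1.6)/100 = 0.084 > ground target (0-1.6)/200
        assert not line_of_sight(g, obs, (1, 22))
        # a 20 m target at 200 m has tangent 0.092 > 0.084: visible
        z[1, 22] = 20.0
        assert line_of_sight(ElevationGrid(spec, z), obs, (1, 22))

    def test_matches_dense_sampling_oracle(self):
        # exact agreement wherever the dense oracle's tangent margin
        # exceeds the half-cell sampling resolution band
        tol = 0.02
        checked = 0
        for seed in (0, 1, 2):
            g = smooth_random_terrain(seed)
            rng = np.random.default_rng(100 + seed)
            obs = ObserverSpec(*rng.uniform(8, 56, 2), 1.6, 100.0)
            for _ in range(20):
                t = (int(rng.integers(0, 64)), int(rng.integers(0, 64)))
                vis_dense, margin = dense_los_margin(g, obs, t)
                if abs(margin) > tol:
                    assert line_of_sight(g, obs, t) == vis_dense
                    checked += 1
        assert checked >= 30  # most targets are decisively classified

    def test_out_of_range_target_raises(self, flat_grid):
        obs = ObserverSpec(20.5, 20.5, 1.6, 3.0)
        with pytest.raises(ValueError, match="max_range"):
            line_of_sight(flat_grid, obs, (0, 0))

    def test_observer_on_nodata_raises_with_hint(self):
        z = np.zeros((5, 5))
        z[2, 2] = np.nan
        g = ElevationGrid(GridSpec(0, 0, 1.0, 5, 5), z)
        with pytest.raises(ValueError, match="fill_nodata"):
            line_of_sight(g, ObserverSpec(2.5, 2.5), (0, 0))


class TestViewshed:
    def test_flat_terrain_gives_lattice_disk(self, flat_grid):
        obs = ObserverSpec(20.5, 20.5, 1.6, 10.0)
        vs = viewshed(flat_grid, obs)
        # brute-force lattice count of centres within 10 m
        expected = sum(
            1
            for r in range(41)
            for c in range(41)
            if math.hypot(r - 20, c - 20) <= 10.0
        )
        assert vs.visible_count == expected
        assert vs.visible_area == expected * 1.0

    def test_range_below_cellsize_leaves_only_observer(self, flat_grid):
        vs = viewshed(flat_grid, ObserverSpec(20.5, 20.5, 1.6, 0.5))
        assert vs.visible_count == 1
        assert vs.mask[20, 20]

    def test_wall_ring_encloses_observer(self):
        spec = GridSpec(0, 0, 1.0, 21, 21)
        z = np.zeros((21, 21))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr or dc:
                    z[10 + dr, 10 + dc] = 100.0
        g = ElevationGrid(spec, z)
        obs = ObserverSpec(10.5, 10.5, 1.6, 50.0)
        fast = viewshed(g, obs)
        naive = viewshed_naive(g, obs)
        np.testing.assert_array_equal(fast.mask, naive.mask)
        # ground beyond the ring is hidden behind the 100 m walls
        outside = fast.mask.copy()
        outside[9:12, 9:12] = False
        assert not outside.any()
        assert fast.mask[10, 10]

    def test_fast_and_naive_agree_exactly_on_random_terrains(self):
        for seed in range(10):
            g = smooth_random_terrain(seed, amp=6.0)
            rng = np.random.default_rng(1000 + seed)
            obs = ObserverSpec(*rng.uniform(5, 59, 2), 1.6, 80.0)
            fast = viewshed(g, obs)
            naive = viewshed_naive(g, obs)
            np.testing.assert_array_equal(fast.mask, naive.mask)
            assert fast.visible_count == naive.visible_count

    def test_observer_outside_extent_raises(self, flat_grid):
        with pytest.raises(ValueError, match="extent"):
            viewshed(flat_grid, ObserverSpec(-5.0, 20.0))


class TestViewshedProperties:
    def test_raising_eye_height_never_shrinks_visible_set(self):
        for seed in (3, 4):
            g = smooth_random_terrain(seed)
            low = viewshed(g, ObserverSpec(30.5, 30.5, 1.6, 60.0))
            high = viewshed(g, ObserverSpec(30.5, 30.5, 8.0, 60.0))
            assert (high.mask | low.mask == high.mask).all()

    def test_shrinking_range_yields_subset_mask(self):
        g = smooth_random_terrain(5)
        big = viewshed(g, ObserverSpec(30.5, 30.5, 1.6, 60.0))
        small = viewshed(g, ObserverSpec(30.5, 30.5, 1.6, 25.0))
        assert (small.mask & big.mask == small.mask).all()

    def test_elevation_outside_visible_set_cannot_add_visible_cells(self):
        base = ElevationGrid(GridSpec(0, 0, 1.0, 31, 31), np.zeros((31, 31)))
        obs = ObserverSpec(15.5, 15.5, 1.6, 10.0)
        before = viewshed(base, obs)
        z = base.z.copy()
        z[~before.mask] += 50.0  # raise terrain only beyond the rim
        after = viewshed(ElevationGrid(base.spec, z), obs)
        inside = before.mask
        assert (after.mask[inside] <= before.mask[inside]).all() or (
            after.mask[inside] == before.mask[inside]
        ).all()

    def test_grazing_tie_counts_as_visible(self):
        # observer eye z=1 at col 0; blocker cell col 2 (earliest sample
        # hits it at s=1.5); target col 4 at z=3, tangent (3-1)/4 = 0.5.
        # Blocker height making its max sample tangent exactly 0.5 is
        # 1 + 0.5*1.5 = 1.75: a tie, which must pass.
        spec = GridSpec(0, 0, 1.0, 3, 5)
        obs = ObserverSpec(0.5, 1.5, 1.0, 10.0)
        z = np.zeros((3, 5))
        z[1, 4] = 3.0
        z[1, 2] = 1.75
        assert line_of_sight(ElevationGrid(spec, z), obs, (1, 4))
        z[1, 2] = 1.76  # just beyond the tie: blocked
        assert not line_of_sight(ElevationGrid(spec, z), obs, (1, 4))
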