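"""Geometry layer: margins, splits, polygons, joining, refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npcctv.core import StructureMask
from npcctv.geometry import (
    MarginSpec,
    SlicePolygon,
    alphashape_join,
    bounding_box,
    chaikin_smooth,
    connected_components,
    equivalent_sphere_diameter,
    expand_mask,
    grid_points,
    morph_refine,
    polygon_to_mask,
    split_inferior_at_centroid,
    subtract_protected,
)

from conftest import make_grid, mask_from, random_blob_mask


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def bruteforce_dilate(mask, margin_mm):
    """Pairwise-distance dilation oracle: O(n*k), voxel-exact."""
    grid = mask.grid
    fg = np.argwhere(mask.voxels) * np.asarray(grid.spacing)
    out = np.zeros(grid.shape, dtype=bool)
    coords = np.indices(grid.shape).reshape(3, -1).T * np.asarray(grid.spacing)
    d2 = ((coords[:, None, :] - fg[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    return (d2 <= margin_mm**2 + 1e-9).reshape(grid.shape)


def floodfill_components(voxels):
    """Independent 26-connectivity component count via BFS."""
    seen = np.zeros_like(voxels, dtype=bool)
    count = 0
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in map(tuple, np.argwhere(voxels)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < voxels.shape[i] for i in range(3)) and voxels[n] and not seen[n]:
                    seen[n] = True
                    stack.append(n)
    return count


def pip_even_odd(px, py, verts):
    """Scalar even-odd crossing test, written independently of the package."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 <= py < y2) or (y2 <= py < y1):
            t = (py - y1) / (y2 - y1)
            if px < x1 + t * (x2 - x1):
                inside = not inside
    return inside


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------

class TestExpandMask:
    def test_zero_margin_identity(self):
        grid = make_grid((8, 8, 8))
        m = mask_from(grid, [(3, 3, 3), (4, 4, 4)])
        assert np.array_equal(expand_mask(m, 0).voxels, m.voxels)

    def test_single_voxel_isotropic_count(self):
        grid = make_grid((9, 9, 9), spacing=(1, 1, 1))
        m = mask_from(grid, [(4, 4, 4)])
        out = expand_mask(m, 3.0)
        assert out.voxel_count == np.count_nonzero(bruteforce_dilate(m, 3.0))
        assert out.voxel_count == 123

    def test_single_voxel_anisotropic_count(self):
        grid = make_grid((9, 9, 9), spacing=(2.5, 1, 1))
        m = mask_from(grid, [(4, 4, 4)])
        out = expand_mask(m, 3.0)
        assert np.array_equal(out.voxels, bruteforce_dilate(m, 3.0))
        assert out.voxel_count == 47

    def test_empty_input_warns_and_returns_empty(self):
        grid = make_grid((4, 4, 4))
        with pytest.warns(UserWarning):
            out = expand_mask(StructureMask.empty("m", grid), 3.0)
        assert out.is_empty

    def test_origin_translation_invariance(self):
        for origin in [(0, 0, 0), (7.3, -2.1, 11.0)]:
            grid = make_grid((8, 8, 8), spacing=(2, 1, 1), origin=origin)
            out = expand_mask(mask_from(grid, [(4, 4, 4)]), 2.5)
            assert out.voxel_count == np.count_nonzero(
                bruteforce_dilate(mask_from(grid, [(4, 4, 4)]), 2.5)
            )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), m1=st.floats(0.5, 3.0), extra=st.floats(0.0, 3.0))
    def test_monotone_in_mask_and_margin(self, seed, m1, extra):
        rng = np.random.default_rng(seed)
        grid = make_grid((10, 10, 10), spacing=(2.0, 1.0, 1.0))
        a = random_blob_mask(grid, rng, n_seeds=3)
        b = StructureMask("b", grid, a.voxels | random_blob_mask(grid, rng, n_seeds=3).voxels)
        ea = expand_mask(a, m1)
        assert not (ea.voxels & ~expand_mask(b, m1).voxels).any()  # A⊆B ⇒ exp(A)⊆exp(B)
        assert not (ea.voxels & ~expand_mask(a, m1 + extra).voxels).any()
        assert not (a.voxels & ~ea.voxels).any()  # input ⊆ output


class TestSubtractProtected:
    def test_margin_spec_validation(self):
        with pytest.raises(ValueError):
            MarginSpec(margin_mm=1.0, min_margin_mm=2.0)

    def test_disjoint_subtrahend_no_op(self):
        grid = make_grid((8, 8, 8))
        t = mask_from(grid, [(1, 1, 1)])
        s = mask_from(grid, [(6, 6, 6)], "oar")
        assert np.array_equal(subtract_protected(t, [s]).voxels, t.voxels)

    def test_gtv_floor_never_removed(self):
        """Expansion into a critical organ is carved out, the GTV never is."""
        grid = make_grid((12, 12, 12))
        gtv = mask_from(grid, [(5, 5, 5), (5, 5, 6)], "gtv")
        target = expand_mask(gtv, 3.0)
        oar = StructureMask("brainstem", grid, np.zeros(grid.shape, dtype=bool))
        oar.voxels[5, 5, 4:9] = True  # slab through the GTV neighbourhood
        out = subtract_protected(target, [oar], protect=gtv, min_margin_mm=0.0)
        assert not (out.voxels & oar.voxels & ~gtv.voxels).any()
        assert (gtv.voxels & ~out.voxels).sum() == 0
        assert not (out.voxels & ~target.voxels).any()  # never adds voxels

    def test_full_protection_is_identity(self):
        grid = make_grid((8, 8, 8))
        t = mask_from(grid, [(3, 3, 3), (3, 3, 4)])
        s = mask_from(grid, [(3, 3, 4)], "oar")
        out = subtract_protected(t, [s], protect=t, min_margin_mm=0.0)
        assert np.array_equal(out.voxels, t.voxels)


class TestSplitInferior:
    def test_symmetric_slab_split_counts(self):
        grid = make_grid((10, 6, 6))
        v = np.zeros(grid.shape, dtype=bool)
        v[2:8, 2:4, 2:4] = True  # 6 identical slices, centroid at 4.5 -> slice 5
        inf, sup = split_inferior_at_centroid(StructureMask("s", grid, v))
        assert inf.voxel_count == 3 * 4 and sup.voxel_count == 3 * 4
        assert not (inf.voxels & sup.voxels).any()
        assert np.array_equal(inf.voxels | sup.voxels, v)

    def test_weighted_centroid_near_heavy_end(self):
        grid = make_grid((16, 4, 4))
        v = np.zeros(grid.shape, dtype=bool)
        v[12:14, :, :] = True  # 2 heavy inferior slices (32 voxels)
        v[2, 0, 0] = True  # 1 voxel 10 slices superior
        # weighted centroid by hand: (32*12.5 + 2) / 33 = 12.18 -> slice 12
        inf, sup = split_inferior_at_centroid(StructureMask("s", grid, v))
        assert inf.voxels[12:14].sum() == 32
        assert sup.voxel_count == 1

    def test_single_slice_degenerate(self):
        grid = make_grid((6, 4, 4))
        m = mask_from(grid, [(3, 1, 1), (3, 2, 2)])
        inf, sup = split_inferior_at_centroid(m)
        assert np.array_equal(inf.voxels, m.voxels)
        assert sup.is_empty

    def test_empty_mask_error(self):
        with pytest.raises(ValueError):
            split_inferior_at_centroid(StructureMask.empty("s", make_grid((4, 4, 4))))


class TestBoundingBoxAndGrid:
    def test_single_voxel_degenerate_box(self):
        grid = make_grid((4, 4, 4), origin=(0.0, 2.0, 3.0))
        m = mask_from(grid, [(1, 2, 1)])
        assert bounding_box(m, 1) == (4.0, 4.0, 4.0, 4.0)

    def test_rectangle_box_center_to_center(self):
        grid = make_grid((2, 10, 10))
        v = np.zeros(grid.shape, dtype=bool)
        v[0, 3:6, 2:7] = True  # 5 cols x 3 rows
        x0, x1, y0, y1 = bounding_box(StructureMask("m", grid, v), 0)
        assert (x1 - x0, y1 - y0) == (4.0, 2.0)

    def test_l_shape_box_encloses_corners(self):
        grid = make_grid((1, 8, 8))
        v = np.zeros(grid.shape, dtype=bool)
        v[0, 1:6, 1] = True
        v[0, 5, 1:6] = True
        assert bounding_box(StructureMask("m", grid, v), 0) == (1.0, 5.0, 1.0, 5.0)

    def test_grid_points_layouts(self):
        pts = grid_points((0, 1, 0, 1), 7, 7)
        assert pts.shape == (49, 2)
        xs = np.unique(pts[:, 0])
        assert np.allclose(np.diff(xs), 1 / 6)
        assert np.allclose(grid_points((2, 2, 3, 3), 7, 7), [[2, 3]] * 49)  # degenerate
        assert np.allclose(
            grid_points((0, 6, 0, 6), 2, 2), [[0, 0], [6, 0], [0, 6], [6, 6]]
        )


class TestChaikin:
    def test_zero_iterations_identity(self):
        poly = SlicePolygon(0, [(0, 0), (1, 0), (1, 1), (0, 1)])
        out = chaikin_smooth(poly, 0)
        assert np.allclose(out.vertices, poly.vertices)

    def test_unit_square_one_iteration_octagon(self):
        poly = SlicePolygon(0, [(0, 0), (1, 0), (1, 1), (0, 1)])
        out = chaikin_smooth(poly, 1)
        expected = np.array(
            [
                [0.25, 0.0], [0.75, 0.0],
                [1.0, 0.25], [1.0, 0.75],
                [0.75, 1.0], [0.25, 1.0],
                [0.0, 0.75], [0.0, 0.25],
            ]
        )
        assert len(out.vertices) == 8
        # same ring up to rotation
        start = np.argmin(((out.vertices - expected[0]) ** 2).sum(axis=1))
        rolled = np.roll(out.vertices, -start, axis=0)
        assert np.allclose(rolled, expected)

    def test_vertex_doubling_and_hull_containment(self):
        import shapely.geometry as sgeom

        rng = np.random.default_rng(5)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 9))
        pts = np.column_stack([np.cos(ang), np.sin(ang)]) * rng.uniform(1, 3, (9, 1))
        poly = SlicePolygon(0, pts)
        k = 3
        out = chaikin_smooth(poly, k)
        assert len(out.vertices) == 9 * 2**k
        hull = sgeom.MultiPoint(pts).convex_hull.buffer(1e-9)
        assert all(hull.contains(sgeom.Point(p)) for p in out.vertices)

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError):
            SlicePolygon(0, [(0, 0), (1, 1), (1, 0), (0, 1)])


class TestPolygonToMask:
    def test_matches_independent_even_odd_oracle(self):
        grid = make_grid((2, 12, 12))
        verts = np.array([(2.25, 2.25), (8.25, 2.25), (8.25, 8.25), (2.25, 8.25)])
        out = polygon_to_mask(SlicePolygon(0, verts), grid)
        for r in range(12):
            for c in range(12):
                assert out.voxels[0, r, c] == pip_even_odd(float(c), float(r), verts)
        assert out.voxel_count == 36  # 6x6 interior centers

    def test_tiny_triangle_no_crash(self):
        grid = make_grid((1, 6, 6))
        out = polygon_to_mask(SlicePolygon(0, [(2.1, 2.1), (2.4, 2.1), (2.2, 2.3)]), grid)
        assert out.voxel_count >= 0

    def test_translation_invariance_on_aligned_grid(self):
        grid = make_grid((1, 16, 16))
        base = np.array([(2.25, 2.25), (6.25, 3.25), (5.25, 7.25)])
        n0 = polygon_to_mask(SlicePolygon(0, base), grid).voxel_count
        n1 = polygon_to_mask(SlicePolygon(0, base + [3.0, 2.0]), grid).voxel_count
        assert n0 == n1

    def test_polygon_outside_grid_rejected(self):
        grid = make_grid((1, 4, 4))
        with pytest.raises(ValueError):
            polygon_to_mask(SlicePolygon(0, [(10, 10), (20, 10), (15, 20)]), grid)


class TestAlphashapeJoin:
    def _two_squares(self, gap_cols):
        grid = make_grid((1, 20, 40 + gap_cols))
        v = np.zeros(grid.shape, dtype=bool)
        v[0, 5:12, 2:10] = True
        v[0, 5:12, 10 + gap_cols : 18 + gap_cols] = True
        return StructureMask("m", grid, v)

    def test_single_component_unchanged(self):
        m = self._two_squares(0)  # actually contiguous
        out = alphashape_join(m, max_gap_mm=15)
        assert np.array_equal(out.voxels, m.voxels)

    def test_nearby_components_become_connected(self):
        from scipy import ndimage

        m = self._two_squares(5)  # 5 mm surface gap
        out = alphashape_join(m, max_gap_mm=15)
        assert (m.voxels & ~out.voxels).sum() == 0  # input preserved
        _, n = ndimage.label(out.voxels[0], structure=np.ones((3, 3), int))
        assert n == 1

    def test_distant_components_retained_unmerged(self):
        from scipy import ndimage

        m = self._two_squares(40)  # 40 mm gap > 15 mm threshold
        out = alphashape_join(m, max_gap_mm=15)
        assert np.array_equal(out.voxels, m.voxels)
        _, n = ndimage.label(out.voxels[0], structure=np.ones((3, 3), int))
        assert n == 2


class TestMorphRefine:
    def test_large_solid_cube_stable_and_idempotent(self):
        """Refinement barely touches a large smooth solid and is idempotent."""
        grid = make_grid((12, 12, 12), spacing=(2.5, 1, 1))
        v = np.zeros(grid.shape, dtype=bool)
        v[2:10, 2:10, 2:10] = True
        m = StructureMask("m", grid, v)
        out = morph_refine(m, open_mm=1.0, close_mm=2.5, min_hole_voxels=0, min_island_voxels=0)
        # only the sharp in-plane corner fibres may be shaved by the opening
        assert (v ^ out.voxels).sum() <= 32
        again = morph_refine(out, open_mm=1.0, close_mm=2.5, min_hole_voxels=0, min_island_voxels=0)
        assert np.array_equal(again.voxels, out.voxels)

    def test_interior_hole_filled(self):
        grid = make_grid((10, 10, 10))
        v = np.zeros(grid.shape, dtype=bool)
        v[2:8, 2:8, 2:8] = True
        v[5, 5, 5] = False
        out = morph_refine(StructureMask("m", grid, v), open_mm=0, close_mm=0,
                           min_hole_voxels=100, min_island_voxels=0)
        assert out.voxels[5, 5, 5]

    def test_speck_removed_unless_kept(self):
        grid = make_grid((14, 14, 14))
        v = np.zeros(grid.shape, dtype=bool)
        v[2:8, 2:8, 2:8] = True
        v[12, 12, 12] = v[12, 12, 11] = True  # 2-voxel speck
        m = StructureMask("m", grid, v)
        out = morph_refine(m, open_mm=0, close_mm=0, min_hole_voxels=0, min_island_voxels=50)
        assert not out.voxels[12, 12, 12]
        keep = mask_from(grid, [(12, 12, 12)], "gtv")
        kept = morph_refine(m, open_mm=0, close_mm=0, min_hole_voxels=0,
                            min_island_voxels=50, keep=keep)
        assert kept.voxels[12, 12, 12]


class TestMeasurements:
    def test_equivalent_sphere_diameter_closed_forms(self):
        grid = make_grid((20, 20, 20))  # 1 mm voxels
        # V = (4/3)pi cm^3 = 4188.79 mm^3 -> d = 2 cm
        n = int(round(4.0 / 3.0 * np.pi * 1000))
        v = np.zeros(grid.shape, dtype=bool)
        v.ravel()[:n] = True
        assert equivalent_sphere_diameter(StructureMask("m", grid, v)) == pytest.approx(2.0, abs=2e-4)
        v2 = np.zeros(grid.shape, dtype=bool)
        v2.ravel()[:1000] = True  # 1 cm^3
        assert equivalent_sphere_diameter(StructureMask("m", grid, v2)) == pytest.approx(1.2407, abs=1e-4)
        assert equivalent_sphere_diameter(StructureMask.empty("m", grid)) == 0.0

    def test_connected_components_vs_floodfill_oracle(self):
        grid = make_grid((10, 10, 10))
        m = mask_from(grid, [(1, 1, 1), (2, 2, 2), (5, 5, 5), (5, 5, 7)])
        comps = connected_components(m)
        assert len(comps) == floodfill_components(m.voxels) == 3
        rng = np.random.default_rng(17)
        blob = StructureMask("b", grid, rng.random(grid.shape) > 0.8)
        comps = connected_components(blob)
        assert len(comps) == floodfill_components(blob.voxels)
        total = np.zeros(grid.shape, dtype=bool)
        for c in comps:
            assert not (total & c.voxels).any()  # pairwise disjoint
            total |= c.voxels
        assert np.array_equal(total, blob.voxels)
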