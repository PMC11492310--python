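"""Spacing-aware 3-D binary-mask geometry.

Every operation works in physical millimetres, never raw voxel counts,
so anisotropic grids (e.g. 2.5 mm slices with 1 mm in-plane pixels) are
handled uniformly.  Margin expansion uses an exact Euclidean distance
transform; planar work (landmark polygons, Chaikin corner cutting,
alpha-shape joining) happens per axial slice in (x, y) mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import shapely
import shapely.geometry as sgeom
from scipy import ndimage
from scipy.spatial import Delaunay
from skimage import morphology as skmorph

from .core import GridMismatchError, ImageGrid, StructureMask, union_masks

__all__ = [
    "SlicePolygon",
    "MarginSpec",
    "expand_mask",
    "subtract_protected",
    "split_inferior_at_centroid",
    "bounding_box",
    "grid_points",
    "chaikin_smooth",
    "polygon_to_mask",
    "alphashape_join",
    "morph_refine",
    "equivalent_sphere_diameter",
    "connected_components",
]


# ---------------------------------------------------------------------------
# planar types
# ---------------------------------------------------------------------------

@dataclass
class SlicePolygon:
    """Closed, implicitly-closing landmark loop on one axial slice.

    ``vertices`` is an (n, 2) array of (x, y) physical mm points, n >= 3,
    with the first vertex not repeated at the end.  Construction asserts
    simplicity (no self-intersection).
    """

    slice_index: int
    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("a slice polygon needs >= 3 (x, y) vertices")
        if np.allclose(self.vertices[0], self.vertices[-1]):
            raise ValueError("first vertex must not be duplicated as the last")
        ring = sgeom.LinearRing(self.vertices)
        if not ring.is_simple:
            raise ValueError("polygon is self-intersecting")

    @property
    def area(self) -> float:
        """Shoelace area (always >= 0)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass(frozen=True)
class MarginSpec:
    """An expansion margin with a protected floor around the gross tumor."""

    margin_mm: float
    min_margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.margin_mm < 0 or self.min_margin_mm < 0:
            raise ValueError("margins must be non-negative")
        if self.min_margin_mm > self.margin_mm:
            raise ValueError("min_margin_mm must not exceed margin_mm")


# ---------------------------------------------------------------------------
# volumetric operations
# ---------------------------------------------------------------------------

def expand_mask(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Isotropic physical expansion by ``margin_mm``.

    A voxel belongs to the result iff its center lies within Euclidean
    distance ``margin_mm`` of some input foreground voxel center
    (computed with an exact distance transform using the grid spacing).
    The input is always a subset of the output.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if mask.is_empty:
        warnings.warn(f"expand_mask: input mask {mask.name!r} is empty", stacklevel=2)
        return mask.copy()
    if margin_mm == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.grid.spacing)
    return StructureMask(mask.name, mask.grid, dist <= margin_mm + 1e-9)


def subtract_protected(
    target: StructureMask,
    subtrahends: Sequence[StructureMask],
    protect: Optional[StructureMask] = None,
    min_margin_mm: float = 0.0,
) -> StructureMask:
    """Remove ``subtrahends`` from ``target`` except inside the protected floor.

    Voxels within ``min_margin_mm`` of the ``protect`` mask (e.g. the
    GTV) are never removed, implementing the protocol's "margin may be
    reduced to as low as 0 mm near critical structures" semantics.
    """
    grid = target.grid
    sub = np.zeros(grid.shape, dtype=bool)
    for s in subtrahends:
        if not s.grid.approx_equal(grid):
            raise GridMismatchError(f"subtrahend {s.name!r} is on a different grid")
        sub |= s.voxels
    if protect is not None and not protect.is_empty:
        if not protect.grid.approx_equal(grid):
            raise GridMismatchError("protect mask is on a different grid")
        protected = expand_mask(protect, min_margin_mm).voxels
        sub &= ~protected
    return StructureMask(target.name, grid, target.voxels & ~sub)


def split_inferior_at_centroid(mask: StructureMask) -> Tuple[StructureMask, StructureMask]:
    """Split a mask by the axial plane through its centroid slice.

    The slice containing the centroid belongs to the inferior part (so
    that "target the inferior section" errs toward coverage).  Returns
    ``(inferior, superior)``.
    """
    if mask.is_empty:
        raise ValueError(f"cannot split empty mask {mask.name!r}")
    slice_idx = np.argwhere(mask.voxels)[:, 0]
    centroid = slice_idx.mean()
    c = int(np.floor(centroid + 0.5))  # slice whose [-0.5, +0.5) span holds the centroid
    s_axis = np.arange(mask.grid.shape[0])
    if mask.grid.inferior_is_high_index:
        inf_sel = s_axis >= c
    else:
        inf_sel = s_axis <= c
    inferior = mask.voxels & inf_sel[:, None, None]
    superior = mask.voxels & ~inf_sel[:, None, None]
    return (
        StructureMask(f"{mask.name}_inferior", mask.grid, inferior),
        StructureMask(f"{mask.name}_superior", mask.grid, superior),
    )


def bounding_box(mask: StructureMask, slice_index: int) -> Tuple[float, float, float, float]:
    """Tight physical box over foreground voxel centers on one slice.

    Returns ``(x_min, x_max, y_min, y_max)`` in mm.
    """
    plane = mask.voxels[slice_index]
    if not plane.any():
        raise ValueError(f"mask {mask.name!r} has no foreground on slice {slice_index}")
    rows, cols = np.nonzero(plane)
    xs = mask.grid.x_of_col(cols)
    ys = mask.grid.y_of_row(rows)
    return float(xs.min()), float(xs.max()), float(ys.min()), float(ys.max())


def grid_points(
    box: Tuple[float, float, float, float], nx: int = 7, ny: int = 7
) -> np.ndarray:
    """``nx * ny`` evenly spaced candidate points covering the box.

    Row-major: y varies slowest.  Degenerate (zero-extent) boxes yield
    coincident points.
    """
    x_min, x_max, y_min, y_max = box
    xs = np.linspace(x_min, x_max, nx)
    ys = np.linspace(y_min, y_max, ny)
    gx, gy = np.meshgrid(xs, ys)  # row-major over y then x
    return np.column_stack([gx.ravel(), gy.ravel()])


# ---------------------------------------------------------------------------
# polygon operations
# ---------------------------------------------------------------------------

def chaikin_smooth(poly: SlicePolygon, iterations: int = 3) -> SlicePolygon:
    """Chaikin corner cutting on a closed polygon.

    Each edge (P_i, P_{i+1}) is replaced by the two points
    Q = 3/4 P_i + 1/4 P_{i+1} and R = 1/4 P_i + 3/4 P_{i+1}, doubling
    the vertex count per iteration.  The output lies inside the convex
    hull of the input.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    v = poly.vertices
    for _ in range(iterations):
        nxt = np.roll(v, -1, axis=0)
        q = 0.75 * v + 0.25 * nxt
        r = 0.25 * v + 0.75 * nxt
        v = np.empty((2 * len(v), 2))
        v[0::2] = q
        v[1::2] = r
    return SlicePolygon(poly.slice_index, v)


def _points_in_polygon(px: np.ndarray, py: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (ray-casting) point-in-polygon test.

    The crossing rule ``(y1 > p) != (y2 > p)`` with a strict x
    comparison gives a consistent half-open boundary convention, so a
    point lying exactly on a shared edge is claimed by exactly one side.
    """
    inside = np.zeros(px.shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = (x2 - x1) * (py - y1) / (y2 - y1) + x1
        inside ^= crosses & (px < x_at)
    return inside


def polygon_to_mask(poly: SlicePolygon, grid: ImageGrid) -> StructureMask:
    """Rasterize a slice polygon: voxel centers inside the loop become foreground.

    Uses the fixed even-odd, half-open boundary convention of
    :func:`_points_in_polygon`.  Raises if the polygon lies outside the
    grid's physical extent or its slice index is out of range.
    """
    if not (0 <= poly.slice_index < grid.shape[0]):
        raise ValueError(f"slice index {poly.slice_index} outside grid")
    x_lo, x_hi = grid.x_of_col(0), grid.x_of_col(grid.shape[2] - 1)
    y_lo, y_hi = grid.y_of_row(0), grid.y_of_row(grid.shape[1] - 1)
    vx, vy = poly.vertices[:, 0], poly.vertices[:, 1]
    pad = max(grid.spacing[1], grid.spacing[2])
    if vx.min() < x_lo - pad or vx.max() > x_hi + pad or vy.min() < y_lo - pad or vy.max() > y_hi + pad:
        raise ValueError("polygon extends outside the grid")

    cols = np.arange(grid.shape[2])
    rows = np.arange(grid.shape[1])
    gx, gy = np.meshgrid(grid.x_of_col(cols), grid.y_of_row(rows))
    inside = _points_in_polygon(gx, gy, poly.vertices)
    out = np.zeros(grid.shape, dtype=bool)
    out[poly.slice_index] = inside
    return StructureMask("polygon", grid, out)


# ---------------------------------------------------------------------------
# alpha-shape island joining
# ---------------------------------------------------------------------------

def _alpha_shape_polygon(points: np.ndarray, alpha: float):
    """2-D alpha shape of a point set as a shapely (Multi)Polygon.

    Keeps Delaunay triangles whose circumradius is at most ``1/alpha``;
    alpha -> 0 recovers the convex hull.  Returns None for degenerate
    inputs (< 3 points or collinear).
    """
    if len(points) < 3:
        return None
    try:
        tri = Delaunay(points)
    except Exception:
        return None
    keep = []
    max_r = np.inf if alpha <= 0 else 1.0 / alpha
    for simplex in tri.simplices:
        pa, pb, pc = points[simplex]
        a = np.linalg.norm(pb - pc)
        b = np.linalg.norm(pa - pc)
        c = np.linalg.norm(pa - pb)
        s = (a + b + c) / 2.0
        area2 = max(s * (s - a) * (s - b) * (s - c), 0.0)
        area = np.sqrt(area2)
        if area < 1e-12:
            continue
        circum_r = a * b * c / (4.0 * area)
        if circum_r <= max_r:
            keep.append(sgeom.Polygon([pa, pb, pc]))
    if not keep:
        return None
    merged = shapely.unary_union(keep)
    return merged if not merged.is_empty else None


def _rasterize_shapely(geom, slice_index: int, grid: ImageGrid) -> np.ndarray:
    cols = np.arange(grid.shape[2])
    rows = np.arange(grid.shape[1])
    gx, gy = np.meshgrid(grid.x_of_col(cols), grid.y_of_row(rows))
    covered = shapely.contains_xy(geom, gx.ravel(), gy.ravel()) | shapely.intersects_xy(
        geom, gx.ravel(), gy.ravel()
    )
    return covered.reshape(gx.shape)


def _boundary_points(plane: np.ndarray, grid: ImageGrid) -> np.ndarray:
    interior = ndimage.binary_erosion(plane, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    boundary = plane & ~interior
    rows, cols = np.nonzero(boundary)
    return np.column_stack([grid.x_of_col(cols), grid.y_of_row(rows)])


def alphashape_join(
    mask: StructureMask, alpha: float = 0.2, max_gap_mm: float = 15.0
) -> StructureMask:
    """Join nearby per-slice islands with an alpha-shape envelope.

    On each axial slice with more than one 8-connected component,
    components whose minimum surface gap is at most ``max_gap_mm`` are
    grouped; each group's boundary points are replaced by a rasterized
    alpha shape (alpha halved until the group actually becomes
    connected, falling back toward the convex hull).  The input is
    always contained in the output; components farther apart than
    ``max_gap_mm`` are retained unmerged.
    """
    out = mask.voxels.copy()
    sy, sx = mask.grid.spacing[1], mask.grid.spacing[2]
    for s in range(mask.grid.shape[0]):
        plane = mask.voxels[s]
        n_fg = plane.sum()
        if n_fg == 0:
            continue
        labels, n = ndimage.label(plane, structure=np.ones((3, 3), dtype=int))
        if n <= 1:
            continue
        # pairwise minimum center-to-center gaps via per-component EDT
        groups = list(range(n))

        def find(i):
            while groups[i] != i:
                groups[i] = groups[groups[i]]
                i = groups[i]
            return i

        dts = []
        for i in range(1, n + 1):
            dts.append(
                ndimage.distance_transform_edt(labels != i, sampling=(sy, sx))
            )
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                gap = dts[i - 1][labels == j].min()
                if gap <= max_gap_mm:
                    ri, rj = find(i - 1), find(j - 1)
                    if ri != rj:
                        groups[ri] = rj
        from collections import defaultdict

        members = defaultdict(list)
        for i in range(n):
            members[find(i)].append(i + 1)
        for comp_ids in members.values():
            if len(comp_ids) < 2:
                continue
            group_plane = np.isin(labels, comp_ids)
            pts = _boundary_points(group_plane, mask.grid)
            a = alpha
            joined = None
            for _ in range(8):
                geom = _alpha_shape_polygon(pts, a)
                if geom is not None:
                    cand = _rasterize_shapely(geom, s, mask.grid) | group_plane
                    _, n_cand = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
                    if n_cand == 1:
                        joined = cand
                        break
                a /= 2.0
            if joined is None:
                hull = sgeom.MultiPoint(pts).convex_hull
                joined = _rasterize_shapely(hull, s, mask.grid) | group_plane
            out[s] |= joined
    return StructureMask(mask.name, mask.grid, out)


# ---------------------------------------------------------------------------
# morphological refinement
# ---------------------------------------------------------------------------

def _ball_structuring_element(radius_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Voxelized ball of physical radius for anisotropic grids."""
    half = [int(np.floor(radius_mm / sp)) for sp in spacing]
    zz, yy, xx = np.mgrid[
        -half[0]: half[0] + 1, -half[1]: half[1] + 1, -half[2]: half[2] + 1
    ]
    d2 = (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
    return d2 <= radius_mm ** 2 + 1e-9


def morph_refine(
    mask: StructureMask,
    open_mm: float = 1.0,
    close_mm: float = 2.5,
    min_hole_voxels: int = 100,
    min_island_voxels: int = 50,
    keep: Optional[StructureMask] = None,
) -> StructureMask:
    """Contour clean-up: opening, closing, hole filling, island removal.

    Opening and closing use physical-radius structuring elements.  Holes
    smaller than ``min_hole_voxels`` are filled; connected components
    smaller than ``min_island_voxels`` are dropped unless they intersect
    ``keep`` (normally the gross tumor union, which must never vanish).
    """
    if open_mm < 0 or close_mm < 0:
        raise ValueError("morphological radii must be >= 0")
    v = mask.voxels
    if open_mm > 0:
        v = ndimage.binary_opening(v, structure=_ball_structuring_element(open_mm, mask.grid.spacing))
    if close_mm > 0:
        v = ndimage.binary_closing(v, structure=_ball_structuring_element(close_mm, mask.grid.spacing))
    if min_hole_voxels > 0:
        # fill cavities STRICTLY smaller than the threshold
        v = skmorph.remove_small_holes(v, max_size=min_hole_voxels - 1)
    if min_island_voxels > 0:
        labels, n = ndimage.label(v, structure=np.ones((3, 3, 3), dtype=int))
        if n:
            sizes = np.bincount(labels.ravel())
            drop = sizes < min_island_voxels
            drop[0] = False
            if keep is not None and not keep.is_empty:
                keep_labels = np.unique(labels[keep.voxels & (labels > 0)])
                drop[keep_labels] = False
            v = v & ~drop[labels]
    if keep is not None and not keep.is_empty:
        v = v | (keep.voxels & mask.voxels)  # opening must not erase kept input voxels
    return StructureMask(mask.name, mask.grid, v)


# ---------------------------------------------------------------------------
# measurements / labelling
# ---------------------------------------------------------------------------

def equivalent_sphere_diameter(mask: StructureMask) -> float:
    """Diameter (cm) of the sphere with the mask's volume; 0 if empty."""
    v_cm3 = mask.volume_mm3 / 1000.0
    if v_cm3 == 0:
        return 0.0
    return float(2.0 * (3.0 * v_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def connected_components(mask: StructureMask) -> List[StructureMask]:
    """26-connected 3-D components, largest first."""
    labels, n = ndimage.label(mask.voxels, structure=np.ones((3, 3, 3), dtype=int))
    comps = [
        StructureMask(f"{mask.name}_cc{i}", mask.grid, labels == i) for i in range(1, n + 1)
    ]
    comps.sort(key=lambda m: -m.voxel_count)
    return comps
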