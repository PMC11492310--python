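"""Core data model: voxel grids, binary structure masks, structure sets.

All masks of a case live on one shared :class:`ImageGrid`.  Arrays are
indexed ``(slice, row, col)``, 0-based.  Physical coordinates are LPS
millimetres: ``x`` increases toward the patient's left (along columns),
``y`` toward posterior (along rows).  The slice axis is the
superior-inferior axis; by default the slice index increases inferiorly
(slice 0 is the most superior slice), recorded on the grid so that
"inferior half" rules are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

__all__ = [
    "ImageGrid",
    "StructureMask",
    "StructureSet",
    "TumorContext",
    "GridMismatchError",
]


class GridMismatchError(ValueError):
    """Raised when masks that must share a grid do not."""


@dataclass(frozen=True)
class ImageGrid:
    """Voxel lattice with physical spacing and origin.

    Parameters
    ----------
    shape : tuple of int
        ``(n_slices, n_rows, n_cols)``.
    spacing : tuple of float
        ``(slice_thickness, row_spacing, col_spacing)`` in mm; all > 0.
    origin : tuple of float
        Physical position (mm) of voxel ``(0, 0, 0)``'s center, ordered
        ``(z, y, x)`` to match the index order.
    inferior_is_high_index : bool
        If True (default), increasing slice index moves inferiorly.
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float] = (2.5, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    inferior_is_high_index: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")

    # -- physical-coordinate helpers -------------------------------------
    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def x_of_col(self, col) -> np.ndarray:
        return self.origin[2] + np.asarray(col) * self.spacing[2]

    def y_of_row(self, row) -> np.ndarray:
        return self.origin[1] + np.asarray(row) * self.spacing[1]

    def z_of_slice(self, s) -> np.ndarray:
        return self.origin[0] + np.asarray(s) * self.spacing[0]

    @property
    def midline_x(self) -> float:
        """x coordinate of the sagittal mid-plane of the grid."""
        return self.origin[2] + (self.shape[2] - 1) * self.spacing[2] / 2.0

    def approx_equal(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and self.inferior_is_high_index == other.inferior_is_high_index
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class StructureMask:
    """A named binary mask on an :class:`ImageGrid`."""

    name: str
    grid: ImageGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask {self.name!r}: voxels shape {self.voxels.shape} "
                f"!= grid shape {self.grid.shape}"
            )

    # -- basic queries ----------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3

    def foreground_coords_mm(self) -> np.ndarray:
        """(n, 3) physical centers (z, y, x) of foreground voxels."""
        idx = np.argwhere(self.voxels)
        return idx * np.asarray(self.grid.spacing) + np.asarray(self.grid.origin)

    def centroid_mm(self) -> np.ndarray:
        if self.is_empty:
            raise ValueError(f"mask {self.name!r} is empty; no centroid")
        return self.foreground_coords_mm().mean(axis=0)

    # -- boolean algebra (grid-checked) -----------------------------------
    def _check(self, other: "StructureMask") -> None:
        if not self.grid.approx_equal(other.grid):
            raise GridMismatchError(
                f"masks {self.name!r} and {other.name!r} are on different grids"
            )

    def union(self, other: "StructureMask", name: Optional[str] = None) -> "StructureMask":
        self._check(other)
        return StructureMask(name or self.name, self.grid, self.voxels | other.voxels)

    def intersect(self, other: "StructureMask", name: Optional[str] = None) -> "StructureMask":
        self._check(other)
        return StructureMask(name or self.name, self.grid, self.voxels & other.voxels)

    def minus(self, other: "StructureMask", name: Optional[str] = None) -> "StructureMask":
        self._check(other)
        return StructureMask(name or self.name, self.grid, self.voxels & ~other.voxels)

    def with_name(self, name: str) -> "StructureMask":
        return StructureMask(name, self.grid, self.voxels)

    def copy(self) -> "StructureMask":
        return StructureMask(self.name, self.grid, self.voxels.copy())

    @classmethod
    def empty(cls, name: str, grid: ImageGrid) -> "StructureMask":
        return cls(name, grid, np.zeros(grid.shape, dtype=bool))


def union_masks(masks: Iterable[StructureMask], name: str, grid: ImageGrid) -> StructureMask:
    """Union an iterable of masks (possibly empty) into one named mask."""
    out = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        if not m.grid.approx_equal(grid):
            raise GridMismatchError(f"mask {m.name!r} is not on the requested grid")
        out |= m.voxels
    return StructureMask(name, grid, out)


@dataclass
class StructureSet:
    """Registry of named binary masks sharing one grid."""

    grid: ImageGrid
    masks: Dict[str, StructureMask] = field(default_factory=dict)

    def add(self, mask: StructureMask) -> None:
        if not mask.grid.approx_equal(self.grid):
            raise GridMismatchError(
                f"mask {mask.name!r} grid differs from the structure-set grid"
            )
        self.masks[mask.name] = mask

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> StructureMask:
        return self.masks[name]

    def get(self, name: str) -> Optional[StructureMask]:
        return self.masks.get(name)

    def names(self) -> List[str]:
        return sorted(self.masks)

    def require(self, names: Iterable[str]) -> None:
        """Raise KeyError listing every required structure that is absent."""
        missing = [n for n in names if n not in self.masks]
        if missing:
            raise KeyError(f"required structures missing from set: {missing}")

    def union_of(self, names: Iterable[str], name: str = "union") -> StructureMask:
        present = [self.masks[n] for n in names if n in self.masks]
        return union_masks(present, name, self.grid)


@dataclass
class TumorContext:
    """Gross tumor volumes plus TNM stage inputs of one case."""

    gtvp: StructureMask
    gtvn_components: List[StructureMask] = field(default_factory=list)
    t_stage: int = 1
    n_stage: int = 0

    def __post_init__(self) -> None:
        if self.t_stage not in (1, 2, 3, 4):
            raise ValueError(f"t_stage must be 1-4, got {self.t_stage}")
        if self.n_stage not in (0, 1, 2, 3):
            raise ValueError(f"n_stage must be 0-3, got {self.n_stage}")
        for comp in self.gtvn_components:
            if comp.is_empty:
                raise ValueError(f"GTVn component {comp.name!r} is empty")

    def gtv_union(self, name: str = "gtv_all") -> StructureMask:
        return union_masks([self.gtvp, *self.gtvn_components], name, self.gtvp.grid)
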