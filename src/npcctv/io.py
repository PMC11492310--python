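"""Reading and writing structure masks.

Interchange format is NIfTI, one binary mask per file, with the filename
stem giving the structure name (resolved through the canonical
registry).  Files are written with a diagonal affine encoding the LPS
physical convention used throughout the package; reading assumes the
same axis orientation (no chirality inference is attempted).

DICOM RT-STRUCT interchange is intentionally not implemented; the tool
consumes per-structure mask volumes from any segmentation source.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import nibabel as nib
import numpy as np

from .core import GridMismatchError, ImageGrid, StructureMask, StructureSet
from .registry import canonical_name

__all__ = [
    "read_mask",
    "write_mask",
    "read_structure_set",
    "resample_to_grid",
]


def _affine_for(grid: ImageGrid) -> np.ndarray:
    sz, sy, sx = grid.spacing
    oz, oy, ox = grid.origin
    zsign = -1.0 if grid.inferior_is_high_index else 1.0
    aff = np.diag([-sx, -sy, zsign * sz, 1.0])
    aff[:3, 3] = (-ox, -oy, zsign * oz)
    return aff


def _grid_from_affine(aff: np.ndarray, ijk_shape: Sequence[int]) -> ImageGrid:
    rot = aff[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-4):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI masks are supported")
    sx, sy, sz = np.abs(np.diag(rot))
    ox, oy = -aff[0, 3], -aff[1, 3]
    inferior_high = aff[2, 2] < 0
    oz = -aff[2, 3] if inferior_high else aff[2, 3]
    ni, nj, nk = ijk_shape
    return ImageGrid(
        shape=(nk, nj, ni),
        spacing=(float(sz), float(sy), float(sx)),
        origin=(float(oz), float(oy), float(ox)),
        inferior_is_high_index=bool(inferior_high),
    )


def write_mask(mask: StructureMask, path: Union[str, Path], format: str = "nifti") -> None:
    """Write a binary mask; only the NIfTI format is supported."""
    if format.lower() not in ("nifti", "nii"):
        raise NotImplementedError(f"unsupported mask format: {format!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(mask.voxels, dtype=np.uint8).transpose(2, 1, 0)  # (i,j,k)=(col,row,slice)
    img = nib.Nifti1Image(data, _affine_for(mask.grid))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_mask(path: Union[str, Path], name: Optional[str] = None, allow_custom: bool = False) -> StructureMask:
    """Read one binary mask from a NIfTI file."""
    path = Path(path)
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    data = np.asarray(img.get_fdata() > 0.5).transpose(2, 1, 0)
    if name is None:
        stem = path.name
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        name = canonical_name(stem, allow_custom=allow_custom)
    return StructureMask(name, grid, data)


def _collect_paths(paths: Union[str, Path, Iterable[Union[str, Path]]]) -> List[Path]:
    if isinstance(paths, (str, Path)):
        p = Path(paths)
        if p.is_dir():
            found = sorted(p.glob("*.nii")) + sorted(p.glob("*.nii.gz"))
            if not found:
                raise FileNotFoundError(f"no NIfTI masks found in directory {p}")
            return found
        return [p]
    return [Path(p) for p in paths]


def read_structure_set(
    paths: Union[str, Path, Iterable[Union[str, Path]]],
    grid_policy: str = "strict",
    reference_grid: Optional[ImageGrid] = None,
    allow_custom: bool = False,
) -> StructureSet:
    """Read a collection of mask files into one :class:`StructureSet`.

    ``grid_policy`` is ``"strict"`` (all file grids must be identical) or
    ``"resample"`` (nearest-neighbour resampling onto ``reference_grid``,
    defaulting to the first file's grid).
    """
    if grid_policy not in ("strict", "resample"):
        raise ValueError(f"grid_policy must be 'strict' or 'resample', got {grid_policy!r}")
    file_list = _collect_paths(paths)
    masks = [read_mask(p, allow_custom=allow_custom) for p in file_list]
    if not masks:
        raise ValueError("no masks to read")

    ref = reference_grid or masks[0].grid
    sset = StructureSet(grid=ref)
    for m in masks:
        if m.grid.approx_equal(ref):
            sset.add(m)
        elif grid_policy == "strict":
            raise GridMismatchError(
                f"mask {m.name!r} grid differs from the reference grid under 'strict' policy"
            )
        else:
            sset.add(resample_to_grid(m, ref))
    return sset


def resample_to_grid(mask: StructureMask, target: ImageGrid) -> StructureMask:
    """Nearest-neighbour binary resampling in physical coordinates.

    Identity when the grids already match.  Raises if the physical
    extents of source and target are disjoint along any axis.
    """
    if mask.grid.approx_equal(target):
        return StructureMask(mask.name, target, mask.voxels.copy())
    if mask.grid.inferior_is_high_index != target.inferior_is_high_index:
        raise ValueError("cannot resample between opposite slice-axis conventions")

    src = mask.grid
    for ax in range(3):
        s_lo = src.origin[ax] - src.spacing[ax] / 2
        s_hi = src.origin[ax] + (src.shape[ax] - 0.5) * src.spacing[ax]
        t_lo = target.origin[ax] - target.spacing[ax] / 2
        t_hi = target.origin[ax] + (target.shape[ax] - 0.5) * target.spacing[ax]
        if s_hi < t_lo or t_hi < s_lo:
            raise ValueError(
                f"source and target grids have disjoint physical extents on axis {ax}"
            )

    out = np.zeros(target.shape, dtype=bool)
    # nearest source index per target axis, or -1 when outside the source lattice
    idx_per_axis = []
    inside_per_axis = []
    for ax in range(3):
        centers = target.origin[ax] + np.arange(target.shape[ax]) * target.spacing[ax]
        cont = (centers - src.origin[ax]) / src.spacing[ax]
        nearest = np.floor(cont + 0.5).astype(int)
        inside = (nearest >= 0) & (nearest < src.shape[ax])
        idx_per_axis.append(np.clip(nearest, 0, src.shape[ax] - 1))
        inside_per_axis.append(inside)
    iz, iy, ix = idx_per_axis
    mz, my, mx = inside_per_axis
    vals = mask.voxels[np.ix_(iz, iy, ix)]
    valid = mz[:, None, None] & my[None, :, None] & mx[None, None, :]
    out = vals & valid
    return StructureMask(mask.name, target, out)
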