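"""Contour comparison metrics: Dice similarity and mean surface distance.

DSC = 2|A ∩ B| / (|A| + |B|), dimensionless in [0, 1].

MSD is the symmetric average of the two directed mean nearest-surface
distances, in mm, where a surface voxel is a foreground voxel with at
least one face-adjacent (6-connected) background neighbour and
distances are measured between voxel centers in physical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import GridMismatchError, StructureMask

__all__ = ["EvalResult", "dsc", "msd", "surface_coords", "evaluate_pairs"]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class EvalResult:
    structure: str
    dsc: float
    msd_mm: Optional[float]
    volume_test_mm3: float
    volume_reference_mm3: float


def _check_grids(a: StructureMask, b: StructureMask) -> None:
    if not a.grid.approx_equal(b.grid):
        raise GridMismatchError(
            f"masks {a.name!r} and {b.name!r} are on different grids"
        )


def dsc(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient; two empty masks agree perfectly (1.0)."""
    _check_grids(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        return 1.0
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)


def surface_coords(mask: StructureMask) -> np.ndarray:
    """(n, 3) physical mm centers of the mask's surface voxels."""
    eroded = ndimage.binary_erosion(mask.voxels, structure=_FACE_STRUCT, border_value=0)
    surf = mask.voxels & ~eroded
    idx = np.argwhere(surf)
    return idx * np.asarray(mask.grid.spacing) + np.asarray(mask.grid.origin)


def msd(a: StructureMask, b: StructureMask) -> float:
    """Symmetric mean surface distance in mm; raises on empty input."""
    _check_grids(a, b)
    if a.is_empty or b.is_empty:
        raise ValueError("mean surface distance is undefined for empty masks")
    pa, pb = surface_coords(a), surface_coords(b)
    d_ab = cKDTree(pb).query(pa)[0].mean()
    d_ba = cKDTree(pa).query(pb)[0].mean()
    return float((d_ab + d_ba) / 2.0)


def evaluate_pairs(
    test: Dict[str, StructureMask], reference: Dict[str, StructureMask]
) -> pd.DataFrame:
    """DSC/MSD table over the structures named in both mappings.

    MSD is left missing (NaN) when either mask is empty.
    """
    rows: List[dict] = []
    for name in sorted(set(test) & set(reference)):
        t, r = test[name], reference[name]
        pair_msd = None if (t.is_empty or r.is_empty) else msd(t, r)
        rows.append(
            {
                "structure": name,
                "dsc": dsc(t, r),
                "msd_mm": pair_msd,
                "volume_test_mm3": t.volume_mm3,
                "volume_reference_mm3": r.volume_mm3,
            }
        )
    return pd.DataFrame(rows)
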