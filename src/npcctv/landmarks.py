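"""Landmark engine: axial grouping, landmark selection, CTV3p construction.

The intermediate-dose primary target (CTV3p) is built slice-by-slice:
structures present on a slice determine an anatomical group; each
grouped structure contributes landmark points chosen from a 7x7
candidate grid over its bounding box according to a data-driven rule
table; the landmarks are joined into a polygon, smoothed by Chaikin
corner cutting, rasterized, and finally merged with the volumetric
expansion of CTV1p, the stage-dependent sphenoid target and the whole
nasopharynx.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import yaml

from .core import ImageGrid, StructureMask, StructureSet, union_masks
from .geometry import (
    SlicePolygon,
    bounding_box,
    chaikin_smooth,
    expand_mask,
    grid_points,
    polygon_to_mask,
    split_inferior_at_centroid,
)

log = logging.getLogger(__name__)

__all__ = [
    "AXIAL_GROUPS",
    "AxialGroupAssignment",
    "LandmarkRule",
    "GtvpLocalization",
    "load_landmark_rules",
    "sphenoid_target",
    "localize_gtvp",
    "assign_axial_groups",
    "select_landmarks",
    "build_slice_polygon",
    "build_ctv3p",
]


# Axial structure groups, superior groups carrying higher numbers.
AXIAL_GROUPS: Dict[int, Set[str]] = {
    1: {"LN_RP_L", "LN_RP_R", "pterygoid_fossa_L", "pterygoid_fossa_R"},
    2: {
        "mastoid_L",
        "mastoid_R",
        "LN_RP_L",
        "LN_RP_R",
        "pterygoid_fossa_L",
        "pterygoid_fossa_R",
        "nasopharynx",
    },
    3: {"LN_RP_L", "LN_RP_R", "pterygoid_fossa_L", "pterygoid_fossa_R", "nasopharynx"},
    4: {"clivus", "pterygoid_fossa_L", "pterygoid_fossa_R", "nasopharynx"},
    5: {
        "clivus",
        "pterygoid_fossa_L",
        "pterygoid_fossa_R",
        "nasopharynx",
        "maxillary_sinus_L",
        "maxillary_sinus_R",
    },
    6: {"clivus", "maxillary_sinus_L", "maxillary_sinus_R", "sphenoid_sinus"},
    7: {"maxillary_sinus_L", "maxillary_sinus_R", "sphenoid_sinus"},
    8: {"sphenoid_sinus"},
}

_GROUPED_STRUCTURES: Set[str] = set().union(*AXIAL_GROUPS.values())

# Structures whose primary-tumor overlap is recorded during localization.
GTVP_TOUCH_STRUCTURES = [
    "clivus",
    "skull_base",
    "pterygoid_fossa_L",
    "pterygoid_fossa_R",
    "sphenoid_sinus",
    "nasal_cavity",
    "maxillary_sinus_L",
    "maxillary_sinus_R",
]


@dataclass
class AxialGroupAssignment:
    slice_index: int
    group_id: int
    present_structures: Set[str]


@dataclass
class LandmarkRule:
    """Fractional anchor positions inside a structure's slice bounding box."""

    structure: str
    applicable_groups: Set[int]
    anchors: List[Tuple[float, float]]
    anchors_invaded: Optional[List[Tuple[float, float]]] = None
    lateral_when_involved: bool = False

    def __post_init__(self) -> None:
        for fx, fy in list(self.anchors) + list(self.anchors_invaded or []):
            if not (0.0 <= fx <= 1.0 and 0.0 <= fy <= 1.0):
                raise ValueError(
                    f"rule for {self.structure!r}: anchor ({fx}, {fy}) outside [0,1]^2"
                )


@dataclass
class GtvpLocalization:
    """Sagittal-plane side and anatomic-invasion summary of the primary tumor."""

    confined_side: str  # "left" | "right" | "bilateral"
    touches: Set[str] = field(default_factory=set)

    @property
    def invades_clivus(self) -> bool:
        return "clivus" in self.touches

    def side_involved(self, side: str) -> bool:
        return self.confined_side in (side, "bilateral")


def load_landmark_rules(path: Optional[Path] = None) -> List[LandmarkRule]:
    """Load the landmark rule table (shipped default or user override)."""
    if path is None:
        with resources.files("npcctv.data").joinpath("landmark_rules.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    rules = []
    for entry in raw["rules"]:
        rules.append(
            LandmarkRule(
                structure=entry["structure"],
                applicable_groups=set(entry["groups"]),
                anchors=[tuple(a) for a in entry["anchors"]],
                anchors_invaded=[tuple(a) for a in entry["anchors_invaded"]]
                if "anchors_invaded" in entry
                else None,
                lateral_when_involved=bool(entry.get("lateral_when_involved", False)),
            )
        )
    return rules


# ---------------------------------------------------------------------------
# stage-dependent sphenoid targeting
# ---------------------------------------------------------------------------

def sphenoid_target(sphenoid: StructureMask, t_stage: int) -> StructureMask:
    """Sphenoid coverage: inferior half for T1-T2, whole sinus for T3-T4."""
    if sphenoid.is_empty:
        raise ValueError("sphenoid sinus mask is empty")
    if t_stage not in (1, 2, 3, 4):
        raise ValueError(f"t_stage must be 1-4, got {t_stage}")
    if t_stage >= 3:
        return sphenoid.copy()
    inferior, _ = split_inferior_at_centroid(sphenoid)
    return inferior.with_name(sphenoid.name)


# ---------------------------------------------------------------------------
# localization
# ---------------------------------------------------------------------------

def _side_of(mask: StructureMask, midline_x: float, bilateral_frac: float = 0.05) -> str:
    """Sagittal side of a mask: left / right / bilateral (>= 5% each side).

    LPS convention: x increases toward the patient's left, so voxels
    with x > midline are on the left.
    """
    xs = mask.grid.x_of_col(np.argwhere(mask.voxels)[:, 2])
    left_frac = float((xs > midline_x).mean())
    right_frac = 1.0 - left_frac
    if left_frac >= bilateral_frac and right_frac >= bilateral_frac:
        return "bilateral"
    return "left" if left_frac > right_frac else "right"


def localize_gtvp(
    gtvp: StructureMask,
    structures: StructureSet,
    midline_x: Optional[float] = None,
) -> GtvpLocalization:
    """Locate the primary tumor: sagittal side and overlapped structures."""
    if gtvp.is_empty:
        raise ValueError("GTVp mask is empty")
    if midline_x is None:
        midline_x = gtvp.grid.midline_x
    side = _side_of(gtvp, midline_x)
    touches = {
        name
        for name in GTVP_TOUCH_STRUCTURES
        if name in structures and bool((gtvp.voxels & structures[name].voxels).any())
    }
    return GtvpLocalization(confined_side=side, touches=touches)


# ---------------------------------------------------------------------------
# axial grouping
# ---------------------------------------------------------------------------

def assign_axial_groups(structures: StructureSet) -> List[AxialGroupAssignment]:
    """Assign each axial slice to at most one structure group.

    A group matches a slice when every one of its structures has
    foreground there.  Because some group structure lists are subsets of
    others, the matched group is the one with the LARGEST fully-present
    structure set (ties broken toward the higher group number); this
    keeps every group reachable and depends only on slice-wise presence.
    """
    n_slices = structures.grid.shape[0]
    presence: Dict[str, np.ndarray] = {}
    for name in _GROUPED_STRUCTURES:
        if name in structures:
            presence[name] = structures[name].voxels.any(axis=(1, 2))
    out: List[AxialGroupAssignment] = []
    for s in range(n_slices):
        present = {name for name, p in presence.items() if p[s]}
        best: Optional[int] = None
        best_size = 0
        for gid in sorted(AXIAL_GROUPS):  # ascending: later (higher) gid wins ties
            req = AXIAL_GROUPS[gid]
            if req <= present and len(req) >= best_size:
                best, best_size = gid, len(req)
        if best is not None:
            out.append(AxialGroupAssignment(s, best, present))
    return out


# ---------------------------------------------------------------------------
# landmark selection and polygon construction
# ---------------------------------------------------------------------------

def _snap_to_grid(point: Tuple[float, float], candidates: np.ndarray) -> Tuple[float, float]:
    d2 = (candidates[:, 0] - point[0]) ** 2 + (candidates[:, 1] - point[1]) ** 2
    best = int(np.argmin(d2))
    return float(candidates[best, 0]), float(candidates[best, 1])


def _structure_side(name: str) -> Optional[str]:
    if name.endswith("_L"):
        return "left"
    if name.endswith("_R"):
        return "right"
    return None


def select_landmarks(
    slice_index: int,
    group: AxialGroupAssignment,
    structures: StructureSet,
    loc: GtvpLocalization,
    rules: Sequence[LandmarkRule],
    grid_nx: int = 7,
    grid_ny: int = 7,
    fired: Optional[List[Tuple[str, int]]] = None,
) -> List[Tuple[float, float]]:
    """Landmark (x, y) points for one grouped slice.

    For each structure of the matched group that carries a rule, anchor
    fractions are evaluated on the structure's slice bounding box and
    snapped to the 7x7 candidate grid.  ``fired`` (optional) collects
    ``(structure, slice)`` records for provenance.
    """
    rule_by_structure = {r.structure: r for r in rules}
    landmarks: List[Tuple[float, float]] = []
    for name in sorted(AXIAL_GROUPS[group.group_id]):
        if name not in structures or not structures[name].voxels[slice_index].any():
            continue
        rule = rule_by_structure.get(name)
        if rule is None:
            warnings.warn(f"no landmark rule for structure {name!r}; skipped", stacklevel=2)
            continue
        if group.group_id not in rule.applicable_groups:
            continue
        box = bounding_box(structures[name], slice_index)
        candidates = grid_points(box, grid_nx, grid_ny)
        anchors = rule.anchors
        if rule.anchors_invaded is not None and name in loc.touches:
            anchors = rule.anchors_invaded
        x_min, x_max, y_min, y_max = box
        for fx, fy in anchors:
            side = _structure_side(name)
            if rule.lateral_when_involved and side is not None and loc.side_involved(side):
                fx = 1.0 if side == "left" else 0.0  # shift to the lateral box edge
            x = x_min + fx * (x_max - x_min)
            y = y_min + fy * (y_max - y_min)
            landmarks.append(_snap_to_grid((x, y), candidates))
        if fired is not None:
            fired.append((name, slice_index))
    return landmarks


def build_slice_polygon(
    landmarks: Sequence[Tuple[float, float]], slice_index: int = 0
) -> SlicePolygon:
    """Order landmarks into a simple polygon by angle about their centroid.

    Counter-clockwise angular sort; ties broken by radius, then by input
    order.  Raises on fewer than 3 points or a fully collinear set.
    """
    pts = np.asarray(landmarks, dtype=float)
    if len(pts) < 3:
        raise ValueError("need >= 3 landmarks to form a polygon")
    pts = np.unique(pts, axis=0) if len(np.unique(pts, axis=0)) >= 3 else pts
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("need >= 3 distinct landmarks to form a polygon")
    center = pts.mean(axis=0)
    rel = pts - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    rad = np.hypot(rel[:, 0], rel[:, 1])
    order = np.lexsort((np.arange(len(pts)), rad, ang))
    ring = pts[order]
    area2 = abs(
        np.dot(ring[:, 0], np.roll(ring[:, 1], -1)) - np.dot(ring[:, 1], np.roll(ring[:, 0], -1))
    )
    if area2 < 1e-9:
        raise ValueError("landmarks are collinear; degenerate polygon")
    return SlicePolygon(slice_index, ring)


# ---------------------------------------------------------------------------
# CTV3p
# ---------------------------------------------------------------------------

def build_ctv3p(
    ctv1p: StructureMask,
    structures: StructureSet,
    t_stage: int,
    loc: GtvpLocalization,
    expansion_mm: float = 5.0,
    chaikin_iterations: int = 3,
    rules: Optional[Sequence[LandmarkRule]] = None,
    provenance: Optional[List[dict]] = None,
) -> StructureMask:
    """Intermediate-dose primary CTV.

    Union of (a) the 5 mm volumetric expansion of CTV1p, (b) per-slice
    smoothed landmark polygons over every grouped slice, (c) the
    stage-dependent sphenoid target and (d) the whole nasopharynx.
    """
    grid = ctv1p.grid
    if rules is None:
        rules = load_landmark_rules()
    parts = [expand_mask(ctv1p, expansion_mm)]

    fired: List[Tuple[str, int]] = []
    assignments = assign_axial_groups(structures)
    n_polygons = 0
    for assignment in assignments:
        lms = select_landmarks(
            assignment.slice_index, assignment, structures, loc, rules, fired=fired
        )
        if len(lms) < 3:
            continue
        try:
            poly = build_slice_polygon(lms, assignment.slice_index)
        except ValueError as exc:
            log.warning("slice %d: %s", assignment.slice_index, exc)
            continue
        smooth = chaikin_smooth(poly, chaikin_iterations)
        parts.append(polygon_to_mask(smooth, grid))
        n_polygons += 1

    if "sphenoid_sinus" in structures and not structures["sphenoid_sinus"].is_empty:
        parts.append(sphenoid_target(structures["sphenoid_sinus"], t_stage))
    if "nasopharynx" in structures:
        parts.append(structures["nasopharynx"])

    if provenance is not None:
        provenance.append(
            {
                "step": "build_ctv3p",
                "expansion_mm": expansion_mm,
                "chaikin_iterations": chaikin_iterations,
                "t_stage": t_stage,
                "grouped_slices": len(assignments),
                "polygon_slices": n_polygons,
                "landmark_firings": [{"structure": n, "slice": s} for n, s in fired],
            }
        )
    return union_masks(parts, "CTV3p", grid)
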