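"""Nodal target-volume logic.

Each connected nodal gross-tumor component is localized to a hemineck
(5% bilateral rule on the sagittal mid-plane), assigned its overlapping
lymph-node levels, and sized by equivalent-sphere diameter.  The
aggregate hemineck flags select one of nine coverage scenarios
(shipped as ``data/nodal_scenarios.yaml``) that determine which nodal
levels form the intermediate-dose CTV3n and which are relegated to the
low-dose CTV4.  Small level-Ib nodes (< 2 cm) route to CTV2; every
other node receives a 3 mm high-dose margin (CTV1n), reduced to 0 mm
against critical organs at risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import yaml

from .core import ImageGrid, StructureMask, StructureSet, union_masks
from .geometry import equivalent_sphere_diameter, expand_mask, subtract_protected
from .landmarks import _side_of

__all__ = [
    "NodalComponent",
    "NodalAssessment",
    "ScenarioId",
    "load_scenario_table",
    "assess_nodes",
    "classify_scenario",
    "build_ctv3n_ctv4",
    "build_ctv2",
    "build_ctv1n",
]

SMALL_NODE_CM = 2.0  # equivalent-sphere diameter threshold

_LOW_NECK = {"left": ("LN_IV_L", "LN_Vb_L"), "right": ("LN_IV_R", "LN_Vb_R")}
_IB = ("LN_Ib_L", "LN_Ib_R")


@dataclass
class NodalComponent:
    """Assessment of one connected GTVn component."""

    mask: Optional[StructureMask]
    side: str  # "left" | "right" | "bilateral"
    containing_levels: Set[str]
    equiv_diameter_cm: float

    @property
    def small_node(self) -> bool:
        return self.equiv_diameter_cm <= SMALL_NODE_CM

    @property
    def in_ib(self) -> bool:
        return any(lvl in self.containing_levels for lvl in _IB)

    @property
    def in_low_neck(self) -> bool:
        return any(
            lvl in self.containing_levels for pair in _LOW_NECK.values() for lvl in pair
        )

    @property
    def routed_to_ctv2_small_ib(self) -> bool:
        """Small-Ib routing: strictly below 2 cm; a tie stays high-dose."""
        return self.in_ib and self.equiv_diameter_cm < SMALL_NODE_CM


@dataclass
class NodalAssessment:
    components: List[NodalComponent] = field(default_factory=list)

    def _side_present(self, side: str) -> bool:
        return any(c.side in (side, "bilateral") for c in self.components)

    @property
    def left_present(self) -> bool:
        return self._side_present("left")

    @property
    def right_present(self) -> bool:
        return self._side_present("right")

    def _low_neck(self, side: str) -> bool:
        levels = _LOW_NECK[side]
        return any(
            lvl in c.containing_levels for c in self.components for lvl in levels
        )

    @property
    def low_neck_left(self) -> bool:
        return self._low_neck("left")

    @property
    def low_neck_right(self) -> bool:
        return self._low_neck("right")


@dataclass(frozen=True)
class ScenarioId:
    table3_scenario: int  # 1-9
    table4_scenarios: frozenset  # subset of {1, 2}


def load_scenario_table() -> Dict[int, dict]:
    with resources.files("npcctv.data").joinpath("nodal_scenarios.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {int(k): v for k, v in raw["scenarios"].items()}


def assess_nodes(
    gtvn_components: Sequence[StructureMask],
    structures: StructureSet,
    midline_x: Optional[float] = None,
) -> NodalAssessment:
    """Per-component side, containing nodal levels and size class."""
    comps: List[NodalComponent] = []
    for comp in gtvn_components:
        if comp.is_empty:
            raise ValueError(f"GTVn component {comp.name!r} is empty")
        mid = midline_x if midline_x is not None else comp.grid.midline_x
        side = _side_of(comp, mid)
        levels = {
            name
            for name in structures.names()
            if name.startswith("LN_") and bool((comp.voxels & structures[name].voxels).any())
        }
        comps.append(
            NodalComponent(
                mask=comp,
                side=side,
                containing_levels=levels,
                equiv_diameter_cm=equivalent_sphere_diameter(comp),
            )
        )
    return NodalAssessment(components=comps)


def classify_scenario(a: NodalAssessment) -> ScenarioId:
    """Map hemineck presence / low-neck flags to the coverage scenarios.

    Total and exhaustive over the flag space: every combination of
    side-presence and low-neck involvement yields exactly one scenario.
    """
    left, right = a.left_present, a.right_present
    low_l, low_r = a.low_neck_left, a.low_neck_right

    if not a.components:
        s3 = 1
    elif low_l and low_r:
        s3 = 5
    elif low_l:
        s3 = 6 if right else 8
    elif low_r:
        s3 = 7 if left else 9
    elif left and right:
        s3 = 2
    elif left:
        s3 = 3
    elif right:
        s3 = 4
    else:  # components exist but sided flags empty cannot occur; N0 fallback
        s3 = 1

    t4: Set[int] = set()
    if any(c.routed_to_ctv2_small_ib for c in a.components):
        t4.add(1)
    if any(c.in_low_neck for c in a.components):
        t4.add(2)
    return ScenarioId(table3_scenario=s3, table4_scenarios=frozenset(t4))


def build_ctv3n_ctv4(
    scenario: ScenarioId, structures: StructureSet
) -> Tuple[StructureMask, StructureMask]:
    """Union the nodal-level masks named by the matched scenario."""
    table = load_scenario_table()
    entry = table[scenario.table3_scenario]
    structures.require(entry["ctv3n"] + entry["ctv4"])
    ctv3n = structures.union_of(entry["ctv3n"], name="CTV3n")
    ctv4 = structures.union_of(entry["ctv4"], name="CTV4")
    return ctv3n, ctv4


def build_ctv2(
    assessment: NodalAssessment,
    grid: ImageGrid,
    margin_mm: float = 3.0,
) -> StructureMask:
    """Intermediate-dose nodal CTV2.

    Union of 3 mm expansions of (a) small (< 2 cm) level-Ib components
    and (b) components inside levels IV or Vb; empty when neither
    condition applies.
    """
    parts = []
    for c in assessment.components:
        if c.mask is None:
            continue
        if c.routed_to_ctv2_small_ib or c.in_low_neck:
            parts.append(expand_mask(c.mask, margin_mm))
    return union_masks(parts, "CTV2", grid)


def build_ctv1n(
    assessment: NodalAssessment,
    critical_oars: Sequence[StructureMask],
    grid: ImageGrid,
    margin_mm: float = 3.0,
    min_margin_mm: float = 0.0,
) -> StructureMask:
    """High-dose nodal CTV1n: 3 mm margins with critical-organ carve-outs.

    Components routed to CTV2 by the small-Ib rule are excluded (a node
    is covered by exactly one of CTV1n / CTV2); each remaining node's
    margin is cut back where it meets a critical organ at risk, but
    never inside the gross node itself.
    """
    parts = []
    for c in assessment.components:
        if c.mask is None or c.routed_to_ctv2_small_ib:
            continue
        expanded = expand_mask(c.mask, margin_mm)
        parts.append(
            subtract_protected(expanded, critical_oars, protect=c.mask, min_margin_mm=min_margin_mm)
        )
    return union_masks(parts, "CTV1n", grid)
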