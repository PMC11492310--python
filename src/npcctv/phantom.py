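"""Synthetic head-and-neck phantom generator.

Builds the full canonical structure set as parameterized geometric
solids (boxes, ellipsoids, tubes) at anatomically plausible relative
positions on a 2.5 mm-slice / 1 mm-in-plane grid, plus configurable
primary and nodal gross tumor volumes.  The geometry is schematic, not
atlas-derived: every placement is analytically known, so expected
outputs of the rule pipeline (group assignments, scenario labels, level
unions, margins) can be computed by hand in tests.

Axial extents are chosen so that each of the eight structure groups of
the landmark engine matches on at least one slice.  Laterality-paired
structures are exact mirror images about the sagittal mid-plane before
jitter; seeded jitter (in-plane only, so axial grouping stays exact) is
applied per structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import ImageGrid, StructureMask, StructureSet, TumorContext
from .nodal import ScenarioId

__all__ = ["GtvnPlacement", "PhantomSpec", "ScenarioCase", "generate_phantom", "generate_scenario_suite"]

DEFAULT_SHAPE = (80, 128, 128)
DEFAULT_SPACING = (2.5, 1.0, 1.0)


@dataclass(frozen=True)
class GtvnPlacement:
    level: str  # e.g. "LN_II"
    side: str  # "left" | "right"
    diameter_mm: float = 15.0

    @property
    def level_name(self) -> str:
        return f"{self.level}_{'L' if self.side == 'left' else 'R'}"


@dataclass
class PhantomSpec:
    seed: int = 0
    shape: Tuple[int, int, int] = DEFAULT_SHAPE
    spacing: Tuple[float, float, float] = DEFAULT_SPACING
    t_stage: int = 1
    n_stage: Optional[int] = None  # derived from placements when None
    gtvp_side: str = "left"  # "left" | "right" | "bilateral"
    gtvp_invades_clivus: bool = False
    gtvp_diameter_mm: float = 24.0
    gtvp_center_mm: Optional[Tuple[float, float, float]] = None  # (z, y, x) override
    gtvn: List[GtvnPlacement] = field(default_factory=list)
    jitter_mm: float = 0.5


@dataclass
class ScenarioCase:
    name: str
    structures: StructureSet
    tumor: TumorContext
    expected: ScenarioId


# ---------------------------------------------------------------------------
# geometric primitives (mm coordinates; z expressed in slice index units)
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self, grid: ImageGrid, rng: np.random.Generator, jitter_mm: float):
        self.grid = grid
        self.rng = rng
        self.jitter = jitter_mm
        ns, nr, nc = grid.shape
        self.zz, self.yy, self.xx = np.meshgrid(
            np.arange(ns) * grid.spacing[0],
            np.arange(nr) * grid.spacing[1],
            np.arange(nc) * grid.spacing[2],
            indexing="ij",
        )
        self.masks: Dict[str, StructureMask] = {}

    def _offsets(self) -> Tuple[float, float]:
        # in-plane jitter only: axial slab extents stay deterministic so the
        # structure-group coverage guarantee holds for every seed
        if self.jitter <= 0:
            return 0.0, 0.0
        dy, dx = self.rng.uniform(-self.jitter, self.jitter, size=2)
        return float(dy), float(dx)

    def box(self, name, z0, z1, y0, y1, x0, x1, jitter=True) -> None:
        """Axis-aligned box; z bounds in slice indices (inclusive), y/x in mm."""
        dy, dx = self._offsets() if jitter else (0.0, 0.0)
        sz = self.grid.spacing[0]
        v = (
            (self.zz >= z0 * sz - 1e-9)
            & (self.zz <= z1 * sz + 1e-9)
            & (self.yy >= y0 + dy)
            & (self.yy <= y1 + dy)
            & (self.xx >= x0 + dx)
            & (self.xx <= x1 + dx)
        )
        self.masks[name] = StructureMask(name, self.grid, v)

    def ellipsoid(self, name, zc, yc, xc, rz_mm, ry_mm, rx_mm, jitter=True) -> None:
        """Ellipsoid centered at slice index zc, (yc, xc) mm."""
        dy, dx = self._offsets() if jitter else (0.0, 0.0)
        sz = self.grid.spacing[0]
        v = (
            ((self.zz - zc * sz) / rz_mm) ** 2
            + ((self.yy - (yc + dy)) / ry_mm) ** 2
            + ((self.xx - (xc + dx)) / rx_mm) ** 2
        ) <= 1.0
        self.masks[name] = StructureMask(name, self.grid, v)

    def sphere(self, name, center_mm, radius_mm) -> None:
        zc, yc, xc = center_mm
        v = ((self.zz - zc) ** 2 + (self.yy - yc) ** 2 + (self.xx - xc) ** 2) <= radius_mm ** 2
        self.masks[name] = StructureMask(name, self.grid, v)

    def tube(self, name, z0, z1, yc, xc, r_mm, jitter=True) -> None:
        """Axial cylinder between slice indices z0..z1 (inclusive)."""
        dy, dx = self._offsets() if jitter else (0.0, 0.0)
        sz = self.grid.spacing[0]
        v = (
            (self.zz >= z0 * sz - 1e-9)
            & (self.zz <= z1 * sz + 1e-9)
            & (((self.yy - (yc + dy)) ** 2 + (self.xx - (xc + dx)) ** 2) <= r_mm ** 2)
        )
        self.masks[name] = StructureMask(name, self.grid, v)


def _mirror_x(x: float, width_mm: float = 127.0) -> float:
    return width_mm - x


# nominal GTVp centers (z slice index units converted to mm at 2.5 mm)
def _gtvp_center(spec: PhantomSpec) -> Tuple[float, float, float]:
    if spec.gtvp_center_mm is not None:
        return spec.gtvp_center_mm
    sz = spec.spacing[0]
    # lateral enough that < 5% of the sphere crosses the sagittal mid-plane
    if spec.gtvp_side == "left":
        x = 74.0
    elif spec.gtvp_side == "right":
        x = 53.0
    else:
        x = 63.5
    if spec.gtvp_invades_clivus:
        return (33 * sz, 70.0, x)
    return (38 * sz, 58.0, x)


def generate_phantom(spec: PhantomSpec) -> Tuple[StructureSet, TumorContext]:
    """Generate the full structure set and tumor context for one case.

    Deterministic for a fixed spec (including seed).
    """
    grid = ImageGrid(shape=spec.shape, spacing=spec.spacing)
    rng = np.random.default_rng(spec.seed)
    b = _Builder(grid, rng, spec.jitter_mm)

    # --- central nervous system and skull ---------------------------------
    b.ellipsoid("brain", 8, 60, 63.5, 22.5, 45, 50)
    b.tube("brainstem", 10, 30, 78, 63.5, 6)
    b.box("skull_base", 20, 26, 40, 90, 30, 97)
    b.box("clivus", 24, 35, 72, 84, 52, 75)
    b.tube("spinal_cord", 31, 79, 82, 63.5, 4)
    b.box("c1_vertebral_body", 36, 39, 74, 90, 52, 75)
    b.box("c2_vertebral_body", 40, 44, 74, 90, 52, 75)
    b.box("vertebral_column", 45, 79, 74, 90, 52, 75)

    # --- sensory organs ----------------------------------------------------
    b.ellipsoid("orbit_L", 23, 32, 88, 12, 12, 12)
    b.ellipsoid("orbit_R", 23, 32, _mirror_x(88), 12, 12, 12)
    b.box("optic_nerve_L", 21, 22, 42, 54, 68, 84)
    b.box("optic_nerve_R", 21, 22, 42, 54, _mirror_x(84), _mirror_x(68))
    b.box("optic_chiasm", 20, 22, 54, 60, 56, 71)

    # --- sinuses, airway, pharynx ------------------------------------------
    b.box("sphenoid_sinus", 18, 27, 55, 70, 48, 79)
    b.box("maxillary_sinus_L", 22, 31, 30, 52, 80, 105)
    b.box("maxillary_sinus_R", 22, 31, 30, 52, _mirror_x(105), _mirror_x(80))
    b.box("nasal_cavity", 26, 38, 28, 56, 52, 75)
    b.box("nasopharynx", 30, 43, 58, 74, 48, 79)
    b.box("pterygoid_fossa_L", 30, 46, 45, 60, 82, 94)
    b.box("pterygoid_fossa_R", 30, 46, 45, 60, _mirror_x(94), _mirror_x(82))
    b.box("mastoid_L", 36, 41, 70, 82, 104, 114)
    b.box("mastoid_R", 36, 41, 70, 82, _mirror_x(114), _mirror_x(104))

    # --- glands, larynx, bones ---------------------------------------------
    b.box("parotid_L", 36, 44, 58, 76, 98, 112)
    b.box("parotid_R", 36, 44, 58, 76, _mirror_x(112), _mirror_x(98))
    b.box("mandible", 44, 50, 25, 40, 30, 97)
    b.box("hyoid", 52, 54, 48, 58, 48, 79)
    b.box("larynx", 54, 62, 40, 60, 52, 75)
    b.box("cricoid", 58, 61, 50, 62, 52, 75)

    # --- lymph node levels ---------------------------------------------------
    b.box("LN_RP_L", 34, 47, 76, 84, 74, 82)
    b.box("LN_RP_R", 34, 47, 76, 84, _mirror_x(82), _mirror_x(74))
    b.box("LN_Ib_L", 46, 52, 36, 54, 70, 92)
    b.box("LN_Ib_R", 46, 52, 36, 54, _mirror_x(92), _mirror_x(70))
    b.box("LN_II_L", 42, 52, 58, 80, 76, 96)
    b.box("LN_II_R", 42, 52, 58, 80, _mirror_x(96), _mirror_x(76))
    b.box("LN_III_L", 53, 62, 58, 80, 76, 96)
    b.box("LN_III_R", 53, 62, 58, 80, _mirror_x(96), _mirror_x(76))
    b.box("LN_IV_L", 63, 72, 58, 80, 76, 96)
    b.box("LN_IV_R", 63, 72, 58, 80, _mirror_x(96), _mirror_x(76))
    b.box("LN_Va_L", 45, 58, 82, 98, 76, 96)
    b.box("LN_Va_R", 45, 58, 82, 98, _mirror_x(96), _mirror_x(76))
    b.box("LN_Vb_L", 59, 72, 82, 98, 76, 96)
    b.box("LN_Vb_R", 59, 72, 82, 98, _mirror_x(96), _mirror_x(76))

    sset = StructureSet(grid=grid)
    for m in b.masks.values():
        if m.is_empty:
            raise ValueError(f"phantom structure {m.name!r} is empty; placement exceeds the grid")
        sset.add(m)

    # --- gross tumor volumes -------------------------------------------------
    gb = _Builder(grid, rng, 0.0)
    gb.sphere("GTVp", _gtvp_center(spec), spec.gtvp_diameter_mm / 2.0)
    gtvp = gb.masks["GTVp"]
    if spec.gtvp_center_mm is None:  # built-in placements honour the flag
        if spec.gtvp_invades_clivus:
            if not (gtvp.voxels & sset["clivus"].voxels).any():
                raise ValueError("invading phantom GTVp does not reach the clivus")
        else:
            assert not (gtvp.voxels & sset["clivus"].voxels).any()

    gtvn_masks: List[StructureMask] = []
    for i, placement in enumerate(spec.gtvn):
        level_mask = sset[placement.level_name]
        cz, cy, cx = level_mask.centroid_mm()
        gb.sphere(f"GTVn_{i+1}", (cz, cy, cx), placement.diameter_mm / 2.0)
        node = gb.masks[f"GTVn_{i+1}"]
        if node.is_empty:
            raise ValueError(f"GTVn placement {placement} produced an empty mask")
        gtvn_masks.append(node)

    n_stage = spec.n_stage
    if n_stage is None:
        if not spec.gtvn:
            n_stage = 0
        elif len({p.side for p in spec.gtvn}) > 1:
            n_stage = 2
        elif any(p.level in ("LN_IV", "LN_Vb") for p in spec.gtvn):
            n_stage = 3
        else:
            n_stage = 1

    tumor = TumorContext(
        gtvp=gtvp, gtvn_components=gtvn_masks, t_stage=spec.t_stage, n_stage=n_stage
    )
    return sset, tumor


# ---------------------------------------------------------------------------
# scenario coverage suite
# ---------------------------------------------------------------------------

def generate_scenario_suite(seed: int = 0) -> List[ScenarioCase]:
    """Phantom cases covering all nine nodal scenarios and the CTV2 routes.

    Each case carries its analytically expected scenario label (known by
    construction: node spheres are centered inside their target levels).
    """
    big = 25.0  # equivalent diameter comfortably >= 2 cm after voxelization
    small = 15.0

    def case(name, placements, expected3, expected4, t_stage=2) -> ScenarioCase:
        spec = PhantomSpec(
            seed=seed,
            t_stage=t_stage,
            gtvn=[GtvnPlacement(lvl, side, d) for lvl, side, d in placements],
        )
        sset, tumor = generate_phantom(spec)
        return ScenarioCase(
            name, sset, tumor, ScenarioId(expected3, frozenset(expected4))
        )

    return [
        case("s1_no_nodes", [], 1, set()),
        case("s2_bilateral_upper", [("LN_II", "left", big), ("LN_II", "right", big)], 2, set()),
        case("s3_left_upper", [("LN_II", "left", big)], 3, set()),
        case("s4_right_upper", [("LN_II", "right", big)], 4, set()),
        case(
            "s5_bilateral_low",
            [("LN_IV", "left", big), ("LN_IV", "right", big)],
            5,
            {2},
        ),
        case(
            "s6_bilateral_low_left",
            [("LN_II", "right", big), ("LN_IV", "left", big)],
            6,
            {2},
        ),
        case(
            "s7_bilateral_low_right",
            [("LN_II", "left", big), ("LN_Vb", "right", big)],
            7,
            {2},
        ),
        case("s8_left_low_only", [("LN_IV", "left", big)], 8, {2}),
        case("s9_right_low_only", [("LN_Vb", "right", big)], 9, {2}),
        case("t4_small_ib", [("LN_Ib", "left", small)], 3, {1}),
        case("t4_large_ib", [("LN_Ib", "left", big)], 3, set()),
        case(
            "t4_both_routes",
            [("LN_Ib", "left", small), ("LN_IV", "right", big)],
            7,
            {1, 2},
        ),
    ]
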