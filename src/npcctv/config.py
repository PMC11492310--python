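"""Pipeline configuration: every protocol margin and tunable parameter.

Defaults encode the protocol rules (3 mm high-dose margin, +5 mm to the
intermediate-dose tier, 0/1 mm minimum margins against critical organs)
plus the numerical choices of the geometry layer.  A YAML file with any
subset of these keys overrides the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional

import yaml

__all__ = ["PipelineConfig"]

# Structures removed from every CTV tier (outside protected GTV regions).
DEFAULT_SUBTRACT_STRUCTURES = [
    "brain",
    "spinal_cord",
    "optic_nerve_L",
    "optic_nerve_R",
    "optic_chiasm",
    "orbit_L",
    "orbit_R",
    "vertebral_column",
    "c1_vertebral_body",
    "c2_vertebral_body",
    "hyoid",
    "cricoid",
    "mandible",
]

# Critical organs at risk that cut the high-dose margins back toward 0 mm.
DEFAULT_CRITICAL_OARS = [
    "brainstem",
    "spinal_cord",
    "optic_chiasm",
    "optic_nerve_L",
    "optic_nerve_R",
]

DEFAULT_REQUIRED_STRUCTURES = [
    "nasopharynx",
    "sphenoid_sinus",
    "clivus",
    "LN_II_L",
    "LN_II_R",
    "LN_III_L",
    "LN_III_R",
    "LN_IV_L",
    "LN_IV_R",
    "LN_Va_L",
    "LN_Va_R",
    "LN_Vb_L",
    "LN_Vb_R",
]


@dataclass
class PipelineConfig:
    # protocol margins (mm)
    ctv1p_margin_mm: float = 3.0
    ctv1n_margin_mm: float = 3.0
    ctv2_margin_mm: float = 3.0
    ctv3p_expansion_mm: float = 5.0
    min_margin_high_dose_mm: float = 0.0  # CTV1 floor near critical organs
    min_margin_intermediate_mm: float = 1.0  # CTV3/CTV4 floor

    # landmark / polygon parameters
    chaikin_iterations: int = 3
    landmark_grid_nx: int = 7
    landmark_grid_ny: int = 7
    landmark_rules_path: Optional[str] = None

    # island joining
    alphashape_alpha: float = 0.2  # 1/mm
    alphashape_max_gap_mm: float = 15.0

    # morphological refinement
    morph_open_mm: float = 1.0
    morph_close_mm: float = 2.5
    morph_min_hole_voxels: int = 100
    morph_min_island_voxels: int = 50

    # structure lists
    subtract_structures: List[str] = field(
        default_factory=lambda: list(DEFAULT_SUBTRACT_STRUCTURES)
    )
    critical_oars: List[str] = field(default_factory=lambda: list(DEFAULT_CRITICAL_OARS))
    required_structures: List[str] = field(
        default_factory=lambda: list(DEFAULT_REQUIRED_STRUCTURES)
    )

    # config hooks for protocol rows without an algorithmic specification
    # (cavernous sinus, skull-base foramina, posterior ethmoid); disabled.
    cover_cavernous_sinus: bool = False
    cover_skull_base_foramina: bool = False
    # optional omission of level Ib for T1-2 N0 disease; off by default
    omit_ib_if_t12n0: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
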