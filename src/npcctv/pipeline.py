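"""Pipeline assembly: from structure set + tumor context to the CTV set.

Execution order mirrors the clinical construction sequence: high-dose
primary volume, landmark-based intermediate primary volume, nodal
scenario logic, CTV3 merge, alpha-shape island joining, subtraction of
normal structures (with gross-tumor protection floors), morphological
refinement, and finally the composite envelopes CTV-Expansion
(CTV1 ∪ CTV2) and CTV-Overall (union of all tiers).  Every step is
recorded in a provenance log for auditability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .config import PipelineConfig
from .core import StructureMask, StructureSet, TumorContext, union_masks
from .geometry import alphashape_join, expand_mask, morph_refine, subtract_protected
from .landmarks import build_ctv3p, load_landmark_rules, localize_gtvp
from .nodal import (
    assess_nodes,
    build_ctv1n,
    build_ctv2,
    build_ctv3n_ctv4,
    classify_scenario,
)
from .io import resample_to_grid, write_mask

__all__ = ["CTVSet", "build_ctv1p", "subtract_normal_structures", "run_pipeline"]


@dataclass
class CTVSet:
    """The output target volumes of one case plus the provenance log."""

    ctv1p: StructureMask
    ctv1n: StructureMask
    ctv1: StructureMask
    ctv2: StructureMask
    ctv3p: StructureMask
    ctv3n: StructureMask
    ctv3: StructureMask
    ctv4: StructureMask
    ctv_expansion: StructureMask
    ctv_overall: StructureMask
    provenance: List[dict] = field(default_factory=list)

    def as_dict(self) -> Dict[str, StructureMask]:
        return {
            "CTV1p": self.ctv1p,
            "CTV1n": self.ctv1n,
            "CTV1": self.ctv1,
            "CTV2": self.ctv2,
            "CTV3p": self.ctv3p,
            "CTV3n": self.ctv3n,
            "CTV3": self.ctv3,
            "CTV4": self.ctv4,
            "CTV_Expansion": self.ctv_expansion,
            "CTV_Overall": self.ctv_overall,
        }

    def write(self, out_dir, save_provenance: bool = True) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, mask in self.as_dict().items():
            write_mask(mask, out_dir / f"{name}.nii.gz")
        if save_provenance:
            (out_dir / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


def build_ctv1p(
    gtvp: StructureMask,
    critical_oars: Sequence[StructureMask],
    margin_mm: float = 3.0,
    min_margin_mm: float = 0.0,
) -> StructureMask:
    """High-dose primary CTV: GTVp + 3 mm, cut back against critical organs.

    The gross tumor itself is always retained (protection floor 0 mm).
    """
    if gtvp.is_empty:
        raise ValueError("GTVp is empty; cannot build CTV1p")
    expanded = expand_mask(gtvp, margin_mm)
    out = subtract_protected(expanded, critical_oars, protect=gtvp, min_margin_mm=min_margin_mm)
    return out.with_name("CTV1p")


def subtract_normal_structures(
    ctv: StructureMask,
    structures: StructureSet,
    subtract_names: Sequence[str],
    protect: Optional[StructureMask],
    min_margin_mm: float,
) -> StructureMask:
    """Remove the normal-structure list from one CTV, sparing the GTV floor."""
    present = [structures[n] for n in subtract_names if n in structures]
    return subtract_protected(ctv, present, protect=protect, min_margin_mm=min_margin_mm)


def run_pipeline(
    structures: StructureSet,
    tumor: TumorContext,
    config: Optional[PipelineConfig] = None,
) -> CTVSet:
    """Run the full CTV construction for one case.

    The working grid is the GTVp grid; all other masks are resampled to
    it (nearest neighbour) if needed.  The construction path contains no
    randomness, so repeated runs are bit-identical.
    """
    cfg = config or PipelineConfig()
    grid = tumor.gtvp.grid
    prov: List[dict] = [{"step": "config", "params": cfg.to_dict()}]

    # --- harmonize grids -------------------------------------------------
    if not structures.grid.approx_equal(grid):
        resampled = StructureSet(grid=grid)
        for name in structures.names():
            resampled.add(resample_to_grid(structures[name], grid))
        structures = resampled
        prov.append({"step": "resample_structures", "target_grid": list(grid.shape)})
    structures.require(cfg.required_structures)

    gtvn = [
        c if c.grid.approx_equal(grid) else resample_to_grid(c, grid)
        for c in tumor.gtvn_components
    ]
    gtv_all = union_masks([tumor.gtvp, *gtvn], "gtv_all", grid)
    oars = [structures[n] for n in cfg.critical_oars if n in structures]

    # --- primary volumes -------------------------------------------------
    loc = localize_gtvp(tumor.gtvp, structures)
    prov.append(
        {"step": "localize_gtvp", "confined_side": loc.confined_side, "touches": sorted(loc.touches)}
    )
    ctv1p = build_ctv1p(
        tumor.gtvp, oars, cfg.ctv1p_margin_mm, cfg.min_margin_high_dose_mm
    )
    prov.append({"step": "build_ctv1p", "margin_mm": cfg.ctv1p_margin_mm, "voxels": ctv1p.voxel_count})

    rules = load_landmark_rules(cfg.landmark_rules_path)
    ctv3p = build_ctv3p(
        ctv1p,
        structures,
        tumor.t_stage,
        loc,
        expansion_mm=cfg.ctv3p_expansion_mm,
        chaikin_iterations=cfg.chaikin_iterations,
        rules=rules,
        provenance=prov,
    )

    # --- nodal volumes ----------------------------------------------------
    assessment = assess_nodes(gtvn, structures)
    scenario = classify_scenario(assessment)
    prov.append(
        {
            "step": "classify_scenario",
            "table3_scenario": scenario.table3_scenario,
            "table4_scenarios": sorted(scenario.table4_scenarios),
            "components": [
                {
                    "name": c.mask.name if c.mask else None,
                    "side": c.side,
                    "levels": sorted(c.containing_levels),
                    "equiv_diameter_cm": round(c.equiv_diameter_cm, 3),
                }
                for c in assessment.components
            ],
        }
    )
    ctv3n, ctv4 = build_ctv3n_ctv4(scenario, structures)
    ctv2 = build_ctv2(assessment, grid, cfg.ctv2_margin_mm)
    ctv1n = build_ctv1n(
        assessment, oars, grid, cfg.ctv1n_margin_mm, cfg.min_margin_high_dose_mm
    )

    # --- merge and island joining ----------------------------------------
    ctv1 = ctv1p.union(ctv1n, name="CTV1")
    ctv3 = ctv3p.union(ctv3n, name="CTV3")
    assert (ctv1.voxels == (ctv1p.voxels | ctv1n.voxels)).all()
    assert (ctv3.voxels == (ctv3p.voxels | ctv3n.voxels)).all()
    ctv3 = alphashape_join(ctv3, cfg.alphashape_alpha, cfg.alphashape_max_gap_mm)
    prov.append(
        {
            "step": "alphashape_join",
            "alpha": cfg.alphashape_alpha,
            "max_gap_mm": cfg.alphashape_max_gap_mm,
            "voxels": ctv3.voxel_count,
        }
    )

    # --- normal-structure subtraction and refinement ----------------------
    def _finalize(mask: StructureMask, protect: StructureMask, min_margin: float) -> StructureMask:
        if mask.is_empty:
            return mask
        out = subtract_normal_structures(
            mask, structures, cfg.subtract_structures, protect, min_margin
        )
        out = morph_refine(
            out,
            cfg.morph_open_mm,
            cfg.morph_close_mm,
            cfg.morph_min_hole_voxels,
            cfg.morph_min_island_voxels,
            keep=protect,
        )
        # closing may have re-entered a subtracted structure: re-apply the
        # protected subtraction so the exclusion guarantee holds exactly
        out = subtract_normal_structures(
            out, structures, cfg.subtract_structures, protect, min_margin
        )
        return out

    hi = cfg.min_margin_high_dose_mm
    mid = cfg.min_margin_intermediate_mm
    ctv1p_f = _finalize(ctv1p, gtv_all, hi)
    ctv1n_f = _finalize(ctv1n, gtv_all, hi)
    ctv2_f = _finalize(ctv2, gtv_all, hi)
    ctv3_f = _finalize(ctv3, gtv_all, mid)
    ctv3p_f = _finalize(ctv3p, gtv_all, mid)
    ctv3n_f = _finalize(ctv3n, gtv_all, mid)
    ctv4_f = _finalize(ctv4, gtv_all, mid)
    ctv1_f = ctv1p_f.union(ctv1n_f, name="CTV1")
    prov.append(
        {
            "step": "subtract_and_refine",
            "subtracted": [n for n in cfg.subtract_structures if n in structures],
            "min_margin_high_dose_mm": hi,
            "min_margin_intermediate_mm": mid,
            "morphology": {
                "open_mm": cfg.morph_open_mm,
                "close_mm": cfg.morph_close_mm,
                "min_hole_voxels": cfg.morph_min_hole_voxels,
                "min_island_voxels": cfg.morph_min_island_voxels,
            },
        }
    )

    # --- composites --------------------------------------------------------
    ctv_expansion = ctv1_f.union(ctv2_f, name="CTV_Expansion")
    ctv_overall = union_masks([ctv1_f, ctv2_f, ctv3_f, ctv4_f], "CTV_Overall", grid)
    prov.append(
        {
            "step": "composites",
            "ctv_expansion_voxels": ctv_expansion.voxel_count,
            "ctv_overall_voxels": ctv_overall.voxel_count,
        }
    )

    return CTVSet(
        ctv1p=ctv1p_f.with_name("CTV1p"),
        ctv1n=ctv1n_f.with_name("CTV1n"),
        ctv1=ctv1_f,
        ctv2=ctv2_f.with_name("CTV2"),
        ctv3p=ctv3p_f.with_name("CTV3p"),
        ctv3n=ctv3n_f.with_name("CTV3n"),
        ctv3=ctv3_f.with_name("CTV3"),
        ctv4=ctv4_f.with_name("CTV4"),
        ctv_expansion=ctv_expansion,
        ctv_overall=ctv_overall,
        provenance=prov,
    )
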