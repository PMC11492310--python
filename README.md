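# npcctv

Rule-based, landmark-driven construction of clinical target volumes
(CTVs) for nasopharyngeal cancer (NPC) radiotherapy.

## The problem

Radiotherapy for NPC irradiates not only the visible tumor but also the
regions of suspected microscopic spread. Protocol guidelines (the
NRG-HN001 family of rules) describe these regions prescriptively: the
primary gross tumor volume (GTVp) plus a 3 mm margin forms the
high-dose CTV1p, reduced to 0 mm against critical organs at risk; the
intermediate-dose CTV3p adds 5 mm, the whole nasopharynx, the
stage-dependent part of the sphenoid sinus and the clivus, and
landmark-bounded coverage of the surrounding anatomy; lymph-node levels
are included or relegated to the low-dose tier depending on where the
nodal disease (GTVn) sits in the neck. Encoding these rules as explicit
geometry makes target delineation reproducible, auditable and easy to
re-target to other protocols — unlike learning the contours from
variable hand-drawn examples.

`npcctv` implements that encoding. It consumes binary masks of ~27
head-and-neck structures (from any segmentation source), GTVp/GTVn
masks and the T/N stage, and produces CTV1p/1n/1, CTV2, CTV3p/3n/3,
CTV4 and the composite envelopes CTV-Expansion (CTV1 ∪ CTV2) and
CTV-Overall (the union of all tiers).

## The algorithm

1. **High-dose primary volume.** CTV1p = GTVp ⊕ 3 mm (exact Euclidean
   physical-margin expansion via a distance transform, honouring
   anisotropic voxel spacing), with voxels inside critical organs
   (brainstem, cord, optic apparatus) carved out except within the
   protected 0 mm floor around the GTVp.
2. **Landmark-based intermediate primary volume.** Each axial slice is
   matched to a structure group by which of the retropharyngeal nodes,
   pterygoid fossae, mastoids, nasopharynx, clivus, maxillary and
   sphenoid sinuses appear on it. Each grouped structure contributes
   landmarks from a 7×7 candidate grid over its bounding box — e.g.
   clivus: the anterior-third corners (full anterior corners if
   invaded); maxillary sinuses: lateral edges at the posterior-quarter
   boundary; pterygoid fossae and RP nodes: the anterior mid-line
   point, shifted laterally on the tumor-bearing side. The landmarks
   are ordered into a polygon, smoothed by Chaikin corner cutting
   (1/4–3/4 ratios), rasterized, and united with CTV1p ⊕ 5 mm, the
   sphenoid target (inferior half for T1–2, whole sinus for T3–4) and
   the whole nasopharynx to form CTV3p.
3. **Nodal scenario logic.** Each connected GTVn component is assigned
   a hemineck (5% bilateral rule about the sagittal mid-plane), its
   overlapping nodal levels, and an equivalent-sphere diameter
   d = 2·(3V/4π)^{1/3}. The aggregate flags select one of nine coverage
   scenarios that fix which levels (Ib, II, III, IV, Va, Vb per side)
   form CTV3n and which form the low-dose CTV4. Small (< 2 cm) level-Ib
   nodes route to CTV2 = GTVn ⊕ 3 mm; all other nodes get CTV1n =
   GTVn ⊕ 3 mm with critical-organ carve-outs.
4. **Assembly.** CTV3 = CTV3p ∪ CTV3n; per-slice islands closer than
   15 mm are joined by an alpha-shape envelope; brain, cord, optic
   nerves/chiasm, orbits, vertebral column/bodies, hyoid, cricoid and
   mandible are subtracted from every tier (GTV floors protected at
   0 mm / 1 mm); morphological refinement (opening, closing, hole and
   island removal) cleans the contours; composites are formed last.

Evaluation metrics (Dice similarity coefficient and symmetric mean
surface distance in mm) and a fully synthetic, seeded head-and-neck
phantom generator are included, so the entire pipeline is testable
without patient data.

## Worked example

```python
from npcctv import PhantomSpec, GtvnPlacement, generate_phantom, run_pipeline

spec = PhantomSpec(seed=7, t_stage=2,
                   gtvn=[GtvnPlacement("LN_II", "left", 15.0)])
structures, tumor = generate_phantom(spec)
ctvs = run_pipeline(structures, tumor)
for name, mask in ctvs.as_dict().items():
    print(f"{name:14s} {mask.volume_mm3/1000.0:7.1f} cm^3")
```

prints

```
CTV1p             13.2 cm^3
CTV1n              4.2 cm^3
CTV1              17.4 cm^3
CTV2               0.0 cm^3
CTV3p             88.7 cm^3
CTV3n             77.3 cm^3
CTV3             165.4 cm^3
CTV4              45.5 cm^3
CTV_Expansion     17.4 cm^3
CTV_Overall      210.8 cm^3
```

The T2 primary (12 mm radius sphere, 7.2 cm³) gains a 3 mm margin
(13.2 cm³); the single left level-II node (equivalent diameter 1.5 cm,
not in level Ib) is covered by CTV1n rather than CTV2, so CTV2 is
empty; scenario 3 ("GTVn on the left, no low-neck disease") puts
level Ib-left plus bilateral II/III/Va into CTV3n and both sides of
IV/Vb into CTV4. The provenance log in `ctvs.provenance` records every
step, parameter and landmark firing.

The same pipeline is scriptable from the shell:

```bash
ctv phantom --seed 7 --t-stage 2 --gtvn LN_II:left:15 --out case/
ctv build --structures case/structures --gtvp case/GTVp.nii.gz \
    --gtvn case/GTVn_1.nii.gz --t-stage 2 --n-stage 1 --out case/ctvs
ctv eval --test case/ctvs --reference case/ctvs --out metrics.csv
```

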