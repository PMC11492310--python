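# Methods

This note documents the geometric model behind `npcctv`, the tunable
parameters and their defaults, the numerical conventions, what the
synthetic phantom does and does not emulate, and the design choices
made where the protocol rules leave the geometry open.

## Coordinate and grid conventions

Masks are binary arrays indexed `(slice, row, col)`, 0-based, on a
shared voxel lattice with positive spacing in mm. Physical coordinates
are LPS: `x` increases toward the patient's left along columns, `y`
toward posterior along rows. The slice axis is superior–inferior with
the slice index increasing inferiorly by default; the flag is stored on
the grid so "inferior half" rules are unambiguous on either convention.
All geometry is computed in physical millimetres, never voxel counts,
so 2.5 mm slices with 1 mm pixels are handled uniformly. Interchange is
NIfTI, one mask per file, filename stem resolved through a canonical
structure registry with case-insensitive aliasing and `_L`/`_R`
laterality suffixes. The working grid of a case is the GTVp grid;
other masks are resampled to it by nearest neighbour in physical
coordinates.

## Margin expansion and protected subtraction

A margin expansion of `m` mm marks every voxel whose center lies within
Euclidean distance `m` of a foreground voxel center, computed with an
exact anisotropic distance transform (`scipy.ndimage.
distance_transform_edt` with the grid spacing as sampling). This is
voxel-identical to brute-force pairwise-distance dilation, which the
tests and the acceptance script verify on random masks at three
spacings. Margins are physical because a voxel-count reading would make
the protocol's "3 mm" mean different things in-plane and axially.

Protected subtraction removes a set of structures from a target except
inside the expansion of a protect mask (the gross tumor) by a floor
margin. Protocol floors: 0 mm for the high-dose volumes (CTV1 family
and CTV2), 1 mm for the intermediate/low tiers (CTV3, CTV4). A tie at
the floor distance is kept (inclusive comparison), erring toward tumor
coverage.

## Landmark engine

**Axial grouping.** Eight structure groups tie slice content to
coverage rules (retropharyngeal nodes + pterygoid fossae at the bottom
of the ladder, sphenoid sinus alone at the top). A group matches a
slice when all of its structures have foreground there. Because some
group lists are strict subsets of others (the sphenoid-only group is
contained in every sphenoid-bearing group), precedence by group number
alone would make the larger groups unreachable; the engine therefore
selects the group with the **largest fully-present structure list**,
breaking ties toward the higher (more superior) group number. This is
deterministic, depends only on slice-wise presence, and makes every
group reachable. Missing structures degrade gracefully: affected groups
simply never match.

**Landmark rules are data.** The rule table ships as
`data/landmark_rules.yaml` and can be replaced wholesale to re-target
the tool to another guideline. Each rule gives fractional anchor
positions `(fx, fy)` inside the structure's per-slice bounding box
(`fy` measured from the anterior edge), snapped to the nearest of a
7×7 candidate grid spanning the box. Defaults:

| structure | anchors | rationale |
|---|---|---|
| maxillary sinuses | lateral edges at `fy = 0.75` | posterior quarter targeted; landmarks at that quarter's anterior boundary |
| clivus | corners at `fy = 1/3`; `fy = 0` when invaded | anterior third covered without invasion, whole structure with it |
| RP nodes, pterygoid fossae | anterior mid-line point | anterior coverage along the box's vertical mid-line |
| pterygoid fossae (tumor side) | anchor shifts to the lateral box edge | coverage widens toward the involved side |
| nasopharynx, sphenoid | four box corners | full cross-section coverage |
| mastoids | two lateral corners | lateral landmark anchors |

The maxillary-sinus rule reconciles two protocol phrasings ("posterior
quarter" coverage vs landmarks "within the 1/4 … section along the box
borders") by targeting the posterior quarter and anchoring at its
anterior boundary — the reading under which both statements are
consistent.

**Polygons.** Landmarks on a slice are ordered counter-clockwise by
angle about their centroid (ties by radius, then input order),
validated as simple, smoothed by Chaikin corner cutting (3 iterations
by default; each iteration replaces edge `(P_i, P_{i+1})` with
`3/4 P_i + 1/4 P_{i+1}` and `1/4 P_i + 3/4 P_{i+1}`, doubling the
vertex count and staying inside the input's convex hull), then
rasterized with a fixed even-odd, half-open boundary convention so a
point on a shared edge belongs to exactly one side. Degenerate slices
(< 3 distinct landmarks, collinear sets, non-star configurations)
contribute nothing, with a logged warning. Slices between two assigned
slices are not interpolated.

## Nodal logic

Connected GTVn components are assessed independently: hemineck by the
5% rule (a component is bilateral only if at least 5% of its voxels lie
on each side of the sagittal mid-plane), level membership by ≥ 1 voxel
overlap with the level mask (no distance tolerance), size by
equivalent-sphere diameter from the voxelized volume. The scenario
table (shipped as `data/nodal_scenarios.yaml` for auditability) is a
partition of the four Boolean flags {left present, right present,
low-neck left, low-neck right}; levels II, III and Va are always
bilateral, level Ib enters CTV3n on involved sides, and a hemineck
without gross level-IV/Vb disease routes those levels to CTV4.

Routing between CTV1n and CTV2 uses the strict inequality d < 2 cm for
the small-Ib rule; a node of exactly 2.0 cm therefore stays in the
high-dose CTV1n (the conservative choice at the boundary). A node
routed to CTV2 by this rule is excluded from CTV1n so every gross node
is covered by exactly one high-dose/intermediate volume; nodes in
levels IV/Vb appear in both CTV2 and CTV1n, as the two rules are
independent. The optional omission of level Ib for T1–2 N0 disease is a
config flag, off by default.

## Island joining and refinement

Alpha-shape joining runs per axial slice (consistent with the
slice-wise polygon pipeline; a flag for future 3-D operation exists in
the design but the per-slice route is the default and only mode).
Components whose minimum surface gap is ≤ 15 mm are grouped; each
group's boundary points are triangulated (Delaunay) and triangles with
circumradius ≤ 1/α (α = 0.2 mm⁻¹ by default) are kept and unioned. If
the rasterized envelope fails to connect the group, α is halved —
approaching the convex hull — until it does. Components farther apart
than the gap threshold are retained unmerged: distant islands are never
silently dropped. The input is always a subset of the output.

Morphological refinement applies opening (1 mm), closing (2.5 mm) with
physical-radius ball structuring elements, fills interior holes
< 100 voxels and removes islands < 50 voxels unless they intersect the
gross tumor. Opening may legitimately shave sharp corners; gross tumor
voxels are always re-instated. Because closing can push a contour back
into a subtracted normal structure, the protected subtraction is
re-applied once after refinement — this enforces the invariant that no
final CTV voxel lies inside brain, cord, optic apparatus, orbits,
vertebral column/bodies, hyoid, cricoid or mandible outside the
protected GTV floor, at the cost of a slightly less smooth boundary
along those interfaces.

Pipeline order: primary volumes → nodal volumes → CTV3 merge →
island joining → subtraction → refinement → composites
(CTV-Expansion = CTV1 ∪ CTV2, CTV-Overall = union of all tiers,
computed from the post-subtraction volumes). There is no randomness
anywhere in the construction path, so reruns are bit-identical.

## Evaluation metrics

DSC = 2|A∩B|/(|A|+|B|), with DSC(∅, ∅) defined as 1.0. MSD is the
symmetric average of the two directed mean nearest-surface distances;
surfaces are foreground voxels with a 6-connected background
neighbour, distances between voxel centers in mm (declared in the
output metadata; mesh-based surfaces are not used). MSD is undefined
(an error) for empty masks. The implementation uses k-d trees and is
verified exactly against an O(n²) pairwise oracle.

## Synthetic phantom

The phantom builds all 42 registry structures (27 delineated anatomical
structures plus the 14 nodal-level compartments and the GTVs) as boxes,
ellipsoids and tubes on a 80×128×128 grid at (2.5, 1, 1) mm — the
2.5 mm slice convention of the pipeline. Axial extents are laid out so
that each of the eight structure groups matches on at least one slice;
laterality pairs are exact mirror images about the sagittal mid-plane
before jitter. Per-structure seeded jitter (default 0.5 mm) is applied
in-plane only, so the axial group layout — the property the landmark
engine depends on — is preserved for every seed while in-plane
positions vary. GTVp is a sphere placed lateral enough that a
"confined" placement stays below the 5% bilateral threshold, with an
optional clivus-overlapping variant and a free center override; GTVn
components are spheres centered in their nominal level compartments, so
their level membership and equivalent diameters are known by
construction (voxelization keeps the diameter within 10% of nominal at
the sizes used). A 12-case suite covers all nine nodal scenarios and
all CTV2 routing combinations with analytically expected labels.

What the phantom does **not** emulate: real anatomical shape, contact
relationships and inter-patient variability; partial-volume and
segmentation error in the input masks; non-axis-aligned acquisition.
Passing tests therefore demonstrate that the rules are implemented as
specified — not that the tool's output is clinically acceptable on
patients, which requires expert review. Structure rows of the protocol
with no algorithmic specification (posterior ethmoid sinus, cavernous
sinus, skull-base foramina coverage) are exposed as disabled config
hooks only.

## Problem sizes and defaults

The default phantom grid (80×128×128, ≈1.3 M voxels) runs the full
pipeline in a few seconds; the 12-case scenario suite and the oracle
comparisons (50 random masks ≤ 20³ for dilation, 6 pairs for MSD)
were sized to make every check exact (voxel-for-voxel or to float
precision) while keeping the whole verification run around a minute.

## Known limitations

- DICOM RT-STRUCT import/export is not implemented; the tool consumes
  and produces per-structure NIfTI masks.
- Landmark anchors for the nasopharynx, mastoids and sphenoid are
  declared approximations of coverage practice (box corners); the rule
  table exists precisely so they can be refined without code changes.
- The alpha-shape step operates per slice; a genuinely 3-D point-cloud
  variant is not provided.
- Reading NIfTI assumes axis-aligned (diagonal-affine) volumes in the
  package's LPS orientation; no chirality inference is attempted.
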