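# Landmark rule table for intermediate-dose primary CTV construction.
#
# Anchors are fractional (fx, fy) positions inside the structure's
# per-slice bounding box: fx runs 0 -> 1 from the patient-right edge to
# the patient-left edge (increasing x, LPS), fy runs 0 -> 1 from the
# ANTERIOR edge to the POSTERIOR edge.  Each anchor is snapped to the
# nearest candidate of the 7x7 point grid spanning the box.
#
# The table is data, not code, so it can be re-targeted to other
# contouring guidelines.  Optional fields:
#   anchors_invaded:       used instead of `anchors` when the primary
#                          tumor invades the structure (clivus rule).
#   lateral_when_involved: on the hemineck containing the primary
#                          tumor, the anchor's fx shifts to the lateral
#                          box edge (1.0 for _L structures, 0.0 for _R).
rules:
  - structure: maxillary_sinus_L
    groups: [5, 6, 7]
    # posterior quarter targeted: landmarks on both lateral edges at the
    # anterior boundary of the posterior quarter
    anchors: [[0.0, 0.75], [1.0, 0.75]]
  - structure: maxillary_sinus_R
    groups: [5, 6, 7]
    anchors: [[0.0, 0.75], [1.0, 0.75]]
  - structure: clivus
    groups: [4, 5, 6]
    # anterior-third corners when not invaded; full anterior corners when invaded
    anchors: [[0.0, 0.3333333333], [1.0, 0.3333333333]]
    anchors_invaded: [[0.0, 0.0], [1.0, 0.0]]
  - structure: LN_RP_L
    groups: [1, 2, 3]
    anchors: [[0.5, 0.0]]
  - structure: LN_RP_R
    groups: [1, 2, 3]
    anchors: [[0.5, 0.0]]
  - structure: pterygoid_fossa_L
    groups: [1, 2, 3, 4, 5]
    anchors: [[0.5, 0.0]]
    lateral_when_involved: true
  - structure: pterygoid_fossa_R
    groups: [1, 2, 3, 4, 5]
    anchors: [[0.5, 0.0]]
    lateral_when_involved: true
  - structure: nasopharynx
    groups: [2, 3, 4, 5]
    anchors: [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]
  - structure: mastoid_L
    groups: [2]
    # lateral box corners
    anchors: [[1.0, 0.0], [1.0, 1.0]]
  - structure: mastoid_R
    groups: [2]
    anchors: [[0.0, 0.0], [0.0, 1.0]]
  - structure: sphenoid_sinus
    groups: [6, 7, 8]
    anchors: [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]
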