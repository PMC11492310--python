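# Canonical structure registry for head-and-neck CTV construction.
# Laterality is a "_L"/"_R" suffix on the canonical name; the alias table
# maps common spellings (case-insensitive, space/hyphen tolerant).
structures:
  - brain
  - brainstem
  - clivus
  - skull_base
  - c1_vertebral_body
  - c2_vertebral_body
  - spinal_cord
  - orbit_L
  - orbit_R
  - optic_nerve_L
  - optic_nerve_R
  - optic_chiasm
  - nasopharynx
  - maxillary_sinus_L
  - maxillary_sinus_R
  - sphenoid_sinus
  - nasal_cavity
  - hyoid
  - cricoid
  - mastoid_L
  - mastoid_R
  - pterygoid_fossa_L
  - pterygoid_fossa_R
  - parotid_L
  - parotid_R
  - larynx
  - mandible
  - vertebral_column
  - LN_Ib_L
  - LN_Ib_R
  - LN_II_L
  - LN_II_R
  - LN_III_L
  - LN_III_R
  - LN_IV_L
  - LN_IV_R
  - LN_Va_L
  - LN_Va_R
  - LN_Vb_L
  - LN_Vb_R
  - LN_RP_L
  - LN_RP_R
  - GTVp
  - GTVn

# Whole-name aliases (already normalized: lowercase, "_" separators).
aliases:
  brain_stem: brainstem
  cord: spinal_cord
  spinalcord: spinal_cord
  chiasm: optic_chiasm
  opticchiasm: optic_chiasm
  np: nasopharynx
  naso_pharynx: nasopharynx
  sphenoid: sphenoid_sinus
  gtv_p: GTVp
  gtv_primary: GTVp
  gtv_n: GTVn
  gtv_node: GTVn
  vertebral_bodies: vertebral_column
  c1: c1_vertebral_body
  c2: c2_vertebral_body

# Laterality tokens mapped to the canonical suffix.
laterality:
  L: [l, lt, left]
  R: [r, rt, right]
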