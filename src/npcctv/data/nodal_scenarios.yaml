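# Nodal-coverage scenario matrix for CTV3n / CTV4 construction.
#
# Conditions are expressed over four Boolean hemineck flags derived from
# the nodal gross tumor volume (GTVn):
#   left / right        - GTVn present on that side of the neck
#   low_left / low_right - GTVn inside lymph-node level IV or Vb on that side
# Levels II, III and Va are covered bilaterally in every scenario; a
# hemineck without gross low-neck disease routes its levels IV and Vb to
# the low-dose CTV4 instead of CTV3n.
scenarios:
  1:
    conditions: {left: false, right: false, low_left: false, low_right: false}
    ctv3n: [LN_II_L, LN_II_R, LN_III_L, LN_III_R, LN_Va_L, LN_Va_R]
    ctv4: [LN_IV_L, LN_IV_R, LN_Vb_L, LN_Vb_R]
  2:
    conditions: {left: true, right: true, low_left: false, low_right: false}
    ctv3n: [LN_Ib_L, LN_Ib_R, LN_II_L, LN_II_R, LN_III_L, LN_III_R, LN_Va_L, LN_Va_R]
    ctv4: [LN_IV_L, LN_IV_R, LN_Vb_L, LN_Vb_R]
  3:
    conditions: {left: true, right: false, low_left: false, low_right: false}
    ctv3n: [LN_Ib_L, LN_II_L, LN_II_R, LN_III_L, LN_III_R, LN_Va_L, LN_Va_R]
    ctv4: [LN_IV_L, LN_IV_R, LN_Vb_L, LN_Vb_R]
  4:
    conditions: {left: false, right: true, low_left: false, low_right: false}
    ctv3n: [LN_Ib_R, LN_II_L, LN_II_R, LN_III_L, LN_III_R, LN_Va_L, LN_Va_R]
    ctv4: [LN_IV_L, LN_IV_R, LN_Vb_L, LN_Vb_R]
  5:
    conditions: {left: true, right: true, low_left: true, low_right: true}
    ctv3n: [LN_Ib_L, LN_Ib_R, LN_II_L, LN_II_R, LN_III_L, LN_III_R,
            LN_IV_L, LN_IV_R, LN_Va_L, LN_Va_R, LN_Vb_L, LN_Vb_R]
    ctv4: []
  6:
    conditions: {left: true, right: true, low_left: true, low_right: false}
    ctv3n: [LN_Ib_L, LN_Ib_R, LN_II_L, LN_II_R, LN_III_L, LN_III_R,
            LN_Va_L, LN_Va_R, LN_IV_L, LN_Vb_L]
    ctv4: [LN_IV_R, LN_Vb_R]
  7:
    conditions: {left: true, right: true, low_left: false, low_right: true}
    ctv3n: [LN_Ib_L, LN_Ib_R, LN_II_L, LN_II_R, LN_III_L, LN_III_R,
            LN_Va_L, LN_Va_R, LN_IV_R, LN_Vb_R]
    ctv4: [LN_IV_L, LN_Vb_L]
  8:
    conditions: {left: true, right: false, low_left: true, low_right: false}
    ctv3n: [LN_Ib_L, LN_II_L, LN_II_R, LN_III_L, LN_III_R,
            LN_Va_L, LN_Va_R, LN_IV_L, LN_Vb_L]
    ctv4: [LN_IV_R, LN_Vb_R]
  9:
    conditions: {left: false, right: true, low_left: false, low_right: true}
    ctv3n: [LN_Ib_R, LN_II_L, LN_II_R, LN_III_L, LN_III_R,
            LN_Va_L, LN_Va_R, LN_IV_R, LN_Vb_R]
    ctv4: [LN_IV_L, LN_Vb_L]
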