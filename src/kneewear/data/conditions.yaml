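# Named displacement-control test conditions.
#
# ap_polarity: "anterior" means anterior tibial shift (negative channel
# values, produces femoral rollback with the distal centre of rotation);
# "posterior" means posterior tibial shift (positive channel values).
# The "distal/modified-intermediate" entry is the computational
# polarity-reversal condition used to decouple the effect of the AP input
# direction from the centre-of-rotation position; it has no experimental
# counterpart.
#
# Axial load (max 2600 N) and flexion (0-58 deg) are common to all
# conditions.
conditions:
  distal/high:
    cor_mode: distal
    ap_max_mm: 10.0
    ap_polarity: anterior
    ie_range_deg: [-5.0, 5.0]
  distal/intermediate:
    cor_mode: distal
    ap_max_mm: 5.0
    ap_polarity: anterior
    ie_range_deg: [-5.0, 5.0]
  iso/modified-high:
    cor_mode: iso
    ap_max_mm: 10.0
    ap_polarity: posterior
    ie_range_deg: [-5.0, 5.0]
  iso/modified-intermediate:
    cor_mode: iso
    ap_max_mm: 5.0
    ap_polarity: posterior
    ie_range_deg: [-5.0, 5.0]
  iso/iso:
    cor_mode: iso
    ap_max_mm: 5.0
    ap_polarity: posterior
    ie_range_deg: [-2.0, 5.5]
    ie_profile: standard
  distal/modified-intermediate:
    cor_mode: distal
    ap_max_mm: 5.0
    ap_polarity: posterior
    ie_range_deg: [-5.0, 5.0]
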