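# Geometry presets for the synthetic fixed-bearing cruciate-retaining TKR
# surrogate.  All lengths are millimetres, angles degrees.
#
# These dimensions are generic values representative of a mid-size CR knee;
# they are NOT the proprietary dimensions of any commercial implant (which
# are unavailable).  The surrogate is designed so that the qualitative
# contact behaviour of a minimally constrained fixed-bearing knee is
# reproduced: distinct distal/posterior sagittal radii (so the distal and
# standard gait-rig centres of rotation differ), and a moderately
# conforming dished insert.
units: mm
presets:
  midsize:
    femoral:
      distal_radius_mm: 37.0
      posterior_radius_mm: 15.0
      transition_angle_deg: 40.0
      frontal_radius_mm: 12.0
      condyle_spacing_mm: 46.0
      width_mm: 72.0
    tibial:
      sagittal_dish_radius_mm: 55.0
      anterior_dish_radius_mm: 70.0
      coronal_dish_radius_mm: 18.0
      ap_extent_mm: 44.0
      width_mm: 72.0
      thickness_mm: 9.0
      dish_spacing_mm: 46.0
      mesh_resolution_mm: 1.0
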