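# Default dependence-testing battery: every processing variable is paired
# with every morphometric variable below (3 x 26 = 78 tests).  Edit freely;
# the battery size is derived from this file, never hard-coded.
#
# type: continuous -> per-kidney rank normalization + Anderson-Darling
#       categorical -> chi-squared on the contingency table
#
# Categorical derived variables such as the transplant decision or a
# missing-value indicator can be added, e.g.:
#   - {name: decision, type: categorical}

processing_variables:
  - technique
  - stain
  - medulla_present

morphometric_variables:
  - {name: cortex_area, type: continuous}
  - {name: biopsy_depth, type: continuous}
  - {name: biopsy_width, type: continuous}
  - {name: glomeruli_total, type: continuous}
  - {name: glomeruli_sclerotic, type: continuous}
  - {name: healthy_glomeruli, type: continuous}
  - {name: gs_pct, type: continuous}
  - {name: glomeruli_per_area, type: continuous}
  - {name: healthy_per_area, type: continuous}
  - {name: sclerotic_per_area, type: continuous}
  - {name: if_area, type: continuous}
  - {name: ta_area, type: continuous}
  - {name: if_pct, type: continuous}
  - {name: ta_pct, type: continuous}
  - {name: artery_count, type: continuous}
  - {name: arteriole_count, type: continuous}
  - {name: vessel_count, type: continuous}
  - {name: artery_wall_thickness, type: continuous}
  - {name: artery_lumen_diameter, type: continuous}
  - {name: artery_full_diameter, type: continuous}
  - {name: wall_lumen_ratio, type: continuous}
  - {name: sub_g, type: continuous}
  - {name: sub_if, type: continuous}
  - {name: sub_ta, type: continuous}
  - {name: sub_a, type: continuous}
  - {name: total_score, type: continuous}
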