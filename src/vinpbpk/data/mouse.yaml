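species: mouse
body_weight_kg: 0.025
hematocrit: 0.45
cardiac_output_L_per_h: null
co_allometry:
  coefficient: 14.1
  exponent: 0.75
percent_body_weight:
  brain: 1.65
  bone_marrow: 3.1
  kidney: 1.67
  liver: 5.49
  gut: 4.22
  slowly_perfused: 70.5
  rapidly_perfused: 8.43
  blood: 4.9
percent_cardiac_output:
  brain: 3.3
  bone_marrow: 1.0
  kidney: 9.1
  liver: 2.0
  gut: 13.0
  slowly_perfused: 35.0
  rapidly_perfused: 36.6
lung_percent_body_weight: 0.73
brain_tissue_fraction: 0.97
brain_blood_fraction: 0.03
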