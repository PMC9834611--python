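species: human
body_weight_kg: 70.0
hematocrit: 0.42
cardiac_output_L_per_h: null
co_allometry:
  coefficient: 14.1
  exponent: 0.75
percent_body_weight:
  brain: 2.0
  bone_marrow: 1.1
  kidney: 0.44
  liver: 2.57
  gut: 2.83
  slowly_perfused: 77.3
  rapidly_perfused: 5.86
  blood: 7.9
percent_cardiac_output:
  brain: 11.4
  bone_marrow: 3.0
  kidney: 17.5
  liver: 4.6
  gut: 18.1
  slowly_perfused: 34.3
  rapidly_perfused: 11.1
lung_percent_body_weight: 0.76
brain_tissue_fraction: 0.97
brain_blood_fraction: 0.03
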