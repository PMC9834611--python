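species: dog
body_weight_kg: 25.0
hematocrit: 0.45
cardiac_output_L_per_h: null
co_allometry:
  coefficient: 14.1
  exponent: 0.75
percent_body_weight:
  brain: 0.78
  bone_marrow: 1.2
  kidney: 0.5
  liver: 3.3
  gut: 3.68
  slowly_perfused: 75.8
  rapidly_perfused: 6.53
  blood: 8.2
percent_cardiac_output:
  brain: 2.0
  bone_marrow: 3.0
  kidney: 17.3
  liver: 4.6
  gut: 25.1
  slowly_perfused: 38.0
  rapidly_perfused: 10.0
lung_percent_body_weight: 0.89
brain_tissue_fraction: 0.97
brain_blood_fraction: 0.03
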