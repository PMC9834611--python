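molecular_weight_g_per_mol: 811.0
Kd_tubulin:
  value: 196.08
  unit: nM
binding_capacity_nmol_per_kg:
  brain: 10710.0
  lung: 2580.0
  kidney: 1470.0
  liver: 3510.0
  gut: 1080.0
  slowly_perfused: 900.0
  rapidly_perfused: 3420.0
  bone_marrow: 371.25
  blood: 0.0
partition_coefficients:
  gut: 1.08
  kidney: 3.73
  liver: 2.26
  bone_marrow: 1.0
  brain: 1.21
  blood: 1.0
  lung: 1.0
  slowly_perfused: 1.0
  rapidly_perfused: 1.0
ABCB1_expression_scaling:
  brain: 1.0
  gut: 0.14
  liver: 0.28
  kidney: 0.78
Vm_ABCB1:
  value: 64.54
  unit: nmol/L
Km_ABCB1:
  value: 5760.0
  unit: nmol/L
Vm_met:
  value: 189.6
  unit: umol/L
Km_met:
  value: 9.53
  unit: umol/L
Vm_bil:
  value: 64.54
  unit: nmol/L
Km_bil:
  value: 5760.0
  unit: nmol/L
SF_bil: 0.28
PSA_ml_per_h: 0.379
GFR_fraction: 0.11
fraction_bound_plasma: 0.75
fu: 1.0
scenario: wild_type
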