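# Escitalopram compound parameter file (default fixture).
# Physicochemistry, binding, absorption, per-isoform intrinsic clearances,
# renal and placental clearances. Units noted per field.
name: escitalopram
molecular_weight: 324.39      # g/mol
logp: 1.34                    # octanol:water
compound_type: monoprotic_base
pka: 9.5
blood_to_plasma: 2.0          # B/P
fu_plasma: 0.44               # fraction unbound in plasma
f_absorbed: 1.0               # fa
k_absorption: 0.19            # 1/h
fu_gut: 1.0                   # fraction unbound in enterocytes
q_gut: 5.69                   # L/h
kp_scalar: 0.92               # uniform scalar on predicted Kp
clint_by_isoform:             # uL/min/pmol isoform
  CYP2C19: 0.774
  CYP2D6: 0.505
  CYP3A4: 0.0155
cl_renal_adult: 4.0           # L/h
cl_pdm: 0.80902               # L/h, maternal-placental barrier
cl_pdf: 0.80902               # L/h, placental-fetal barrier
# Lumped unbound gut first-pass intrinsic clearance (L/h). Fixture value
# chosen so that fa * Fg * Fh = 0.80 at gestational week 0, anchored to the
# ~80% oral bioavailability of escitalopram.
clint_gut_unbound: 0.3414
fetal:
  swallowed_volume_ml_per_day: 750.0
  fetal_weight_kg: 3.7
  fetal_gfr_ml_per_min: 4.92
  adult_gfr_ml_per_min: 121.0
  fetal_binding_protein_ratio: 0.37   # fetal AGP as fraction of maternal GW-0
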