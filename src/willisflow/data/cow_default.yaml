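# Default lumped Circle-of-Willis network description.
#
# Vessel lengths/diameters are literature-typical values for a complete
# adult CoW (segment resistances are 1-2 orders of magnitude below the
# Windkessel outlet resistances, so outlet calibration absorbs residual
# geometric mismatch).  Windkessel parameters for the ACA/MCA/PCA outlets
# are published calibrated values; the SCA entries are initial guesses
# (PCA parameters scaled by the target-flow ratio) refined by calibration.
# The clot block describes a fibrin plug occluding the proximal M1-LMCA.

fluid:
  density_kg_m3: 1060.0
  kinematic_viscosity_m2_s: 3.77e-6

segments:
  - {name: LICA,          from: LICA_inlet,    to: LICA_term,     length_mm: 20.0, diameter_mm: 4.5}
  - {name: RICA,          from: RICA_inlet,    to: RICA_term,     length_mm: 20.0, diameter_mm: 4.5}
  - {name: BA,            from: BA_inlet,      to: BA_term,       length_mm: 25.0, diameter_mm: 3.2}
  - {name: M1-LMCA-prox,  from: LICA_term,     to: LM1_prox,      length_mm: 2.0,  diameter_mm: 3.0}
  - {name: M1-LMCA-mid,   from: LM1_prox,      to: LM1_dist,      length_mm: 5.0,  diameter_mm: 3.0}
  - {name: M1-LMCA-dist,  from: LM1_dist,      to: LMCA_out,      length_mm: 13.0, diameter_mm: 3.0}
  - {name: M1-RMCA,       from: RICA_term,     to: RMCA_out,      length_mm: 20.0, diameter_mm: 3.0}
  - {name: A1-LACA,       from: LICA_term,     to: LACA_junction, length_mm: 12.0, diameter_mm: 2.3}
  - {name: A2-LACA,       from: LACA_junction, to: LACA_out,      length_mm: 24.0, diameter_mm: 2.4}
  - {name: A1-RACA,       from: RICA_term,     to: RACA_junction, length_mm: 12.0, diameter_mm: 2.3}
  - {name: A2-RACA,       from: RACA_junction, to: RACA_out,      length_mm: 24.0, diameter_mm: 2.4}
  - {name: AComA,         from: LACA_junction, to: RACA_junction, length_mm: 3.0,  diameter_mm: 1.5}
  - {name: LPComA,        from: LICA_term,     to: LPCA_junction, length_mm: 15.0, diameter_mm: 1.45}
  - {name: RPComA,        from: RICA_term,     to: RPCA_junction, length_mm: 15.0, diameter_mm: 1.45}
  - {name: P1-LPCA,       from: BA_term,       to: LPCA_junction, length_mm: 10.0, diameter_mm: 2.1}
  - {name: P2-LPCA,       from: LPCA_junction, to: LPCA_out,      length_mm: 30.0, diameter_mm: 2.0}
  - {name: P1-RPCA,       from: BA_term,       to: RPCA_junction, length_mm: 10.0, diameter_mm: 2.1}
  - {name: P2-RPCA,       from: RPCA_junction, to: RPCA_out,      length_mm: 30.0, diameter_mm: 2.0}
  - {name: LSCA,          from: BA_term,       to: LSCA_out,      length_mm: 15.0, diameter_mm: 1.48}
  - {name: RSCA,          from: BA_term,       to: RSCA_out,      length_mm: 15.0, diameter_mm: 1.48}

inlets:
  LICA: LICA_inlet
  RICA: RICA_inlet
  BA: BA_inlet

outlets:
  LACA: LACA_out
  LMCA: LMCA_out
  LPCA: LPCA_out
  LSCA: LSCA_out
  RACA: RACA_out
  RMCA: RMCA_out
  RPCA: RPCA_out
  RSCA: RSCA_out

collateral:
  # lumped leptomeningeal element per hemisphere, oriented distal ACA -> distal
  # MCA so that retrograde recruitment after occlusion is a positive flow
  attach:
    ipsilateral:   {from: LACA_out, to: LMCA_out}
    contralateral: {from: RACA_out, to: RMCA_out}
  geometry:
    CS1: {length_mm: 35.5, diameter_mm: 0.75}
    CS2: {length_mm: 35.5, diameter_mm: 1.00}
    CS3: {length_mm: 34.8, diameter_mm: 1.25}
    CS4: {length_mm: 34.8, diameter_mm: 1.50}

clot:
  segment: M1-LMCA-mid
  fiber_radius_nm: 250.0
  fibrin_fraction: 0.18
  length_mm: 5.0
  face_area_proximal_mm2: 7.40
  face_area_distal_mm2: 6.38

windkessel:
  # R1/R2 in Pa.s/m^3, C in m^3/Pa; reference (venous) pressure 0 Pa
  LACA: {R1: 5.748e8, R2: 7.716e9,  C: 2.110e-11}
  LMCA: {R1: 3.096e8, R2: 5.208e9,  C: 6.329e-11}
  LPCA: {R1: 8.664e8, R2: 7.776e9,  C: 3.164e-11}
  LSCA: {R1: 2.490e9, R2: 2.240e10, C: 1.500e-11}
  RACA: {R1: 5.748e8, R2: 7.716e9,  C: 2.110e-11}
  RMCA: {R1: 3.024e8, R2: 5.040e9,  C: 6.329e-11}
  RPCA: {R1: 8.664e8, R2: 7.776e9,  C: 3.164e-11}
  RSCA: {R1: 2.490e9, R2: 2.240e10, C: 1.500e-11}

inflow_ml_min:
  # prescribed inlet mean flows (phase-contrast MRI derived means)
  LICA: 243.07
  RICA: 235.25
  BA: 127.05

targets:
  # clinical mean outlet flows (mL/min) and systemic pressures (mmHg) used
  # by the Windkessel calibration loop; SCA flows have no clinical
  # measurement and use the model-derived 28.1 mL/min
  mean_flow_ml_min:
    LACA: 79.0
    LMCA: 146.0
    LPCA: 61.0
    LSCA: 28.1
    RACA: 86.0
    RMCA: 133.0
    RPCA: 58.0
    RSCA: 28.1
  systolic_mmhg: 130.5
  diastolic_mmhg: 70.4
  tolerance: 0.10

simulation:
  dt_s: 0.001
  duration_s: 6.0
  period_s: 0.857
  n_discard_cycles: 2
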