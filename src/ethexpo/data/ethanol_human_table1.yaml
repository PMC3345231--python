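# Reference human parameter set for the inhaled-ethanol PBPK model.
# Flows, ventilation and Vmax scale as coef * BW^0.75; volumes as
# fraction * BW (1 kg ~ 1 L). Partition coefficients are tissue:air.
body_weight: 70            # kg
cardiac_output_coef: 18    # (L/h)/kg^0.75
alveolar_vent_coef: 18     # (L/h)/kg^0.75
absorbed_fraction: 0.62    # net fractional airway uptake
flow_fractions:            # fraction of cardiac output
  fat: 0.05
  liver: 0.25
  rapid: 0.39
  slow: 0.19
  brain: 0.12
volume_fractions:          # fraction of body volume (total 0.91)
  fat: 0.213
  liver: 0.0257
  rapid: 0.0443
  slow: 0.607
  brain: 0.02
blood_volume_fraction: 0.079   # reference-man blood volume
partition_air:             # tissue:air equilibrium ratios
  blood: 2280
  fat: 226
  liver: 1730
  rapid: 2030
  slow: 1710
  brain: 1870
vmax_coef: 359.5           # (mg/h)/kg^0.75
km: 82.1                   # mg/L, on liver-exit blood
uptake_model: fractional
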