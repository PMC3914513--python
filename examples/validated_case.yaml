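# Baseline process: 100 V across a mashed-potato cylinder initially at
# 279.15 K, with low-but-effective external losses (U = 5 W/m^2/K into
# 13 degC air) on every exterior face, run for 150 s.
geometry:
  radius_m: 0.025
  length_m: 0.18
grid:
  nr: 24
  nz: 48
process:
  applied_voltage_V: 100.0
  drive_mode: constant_voltage
  duration_s: 150.0
  dt_s: 0.5
  T0_K: 279.15
  snapshot_interval_s: 50.0
thermal_bc:
  U_W_m2K: 5.0
  T_inf_K: 286.15
kinetics:
  z_C: 10.0
  D_ref_s: 60.0
  T_ref_K: 333.15
  target_log_reduction: 12.0
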