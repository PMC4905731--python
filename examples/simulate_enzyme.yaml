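# Trajectory export for the reversible enzyme scheme at the reference
# high-dose condition:
#   salclear simulate --config examples/simulate_enzyme.yaml --out-dir traj/
# Writes trajectory.csv with columns time_h,S_mg_L,SE_mg_L,E_mg_L,P_mg_L.

model: enzyme
params:          # affinity parameterisation; koff1/kon2 derived
  KS: 10.44      # mg/L
  KP: 273.5      # mg/L
  koff2: 14.82   # 1/s
  kon1: 3.0      # L/(mg*s)
  ETOT: 1.5e-4   # mg/L
  S0: 335.0      # mg/L
times:
  start: 0.0
  stop: 16.0     # hours
  n: 161
  spacing: linear   # or "log"
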