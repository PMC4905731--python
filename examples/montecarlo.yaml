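# Monte Carlo uncertainty for the condition-C enzyme fit:
#   salclear montecarlo --config examples/montecarlo.yaml --out-dir mc/ data/*.csv
# The fit section is identical to fit_enzyme.yaml; the montecarlo block
# controls the replicate machinery.

model: enzyme
free: [KS, KP, koff2]
fixed:
  kon1: 3.0
  ETOT: 1.5e-4
  G: 0.0
  S0_low: 5.67
  S0_mid: 64.9
  S0_high: 335.0
curve_weight_mode: equalize
n_starts: 5
seed: 0

montecarlo:
  n_reps: 200              # replicates (reference analyses use 1000)
  noise_frac: 0.01         # multiplicative U(-1%, +1%) per observation
  rejection_threshold: 1000  # drop replicates with KS/KP/koff2 above this
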