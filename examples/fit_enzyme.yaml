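# Simultaneous enzyme-model fit with fixed initial concentrations
# (condition "C" of the standard masks). Run as:
#   salclear fit --config examples/fit_enzyme.yaml --out-dir out/ data/low.csv data/mid.csv data/high.csv
# Datasets may instead be listed here under `data:` (paths relative to
# this file); labels come from the file stems and must match the
# S0_<label> parameter names.

model: enzyme

# Parameters to optimize. The full enzyme parameter set is
# KS, KP, koff2, kon1, ETOT, G plus one S0_<label> per dataset;
# free + fixed must cover it exactly.
free: [KS, KP, koff2]

fixed:
  kon1: 3.0        # L/(mg*s); binding assumed fast, not identifiable
  ETOT: 1.5e-4     # mg/L; nominal - enters only via ETOT*koff2
  G: 0.0           # 1/h; product consumption ignored
  S0_low: 5.67     # mg/L, per-group initial concentrations
  S0_mid: 64.9
  S0_high: 335.0

# "equalize" gives each curve weight 1/sum(obs^2) so all dose levels
# contribute comparably; "manual" uses weights carried by the datasets
# (override per label under `curve_weights:`).
curve_weight_mode: equalize

n_starts: 5        # jittered simplex restarts (seeded, deterministic)
max_iter: 2000
seed: 0            # overridden by --seed
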