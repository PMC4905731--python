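# salclear

Enzyme-kinetic modelling of plasma salicylate clearance.

After an oral aspirin dose, acetylsalicylic acid hydrolyses almost
instantly to salicylate (S), which is cleared mainly by enzymatic
conjugation to salicylurate (P) in liver and kidney mitochondria.
Clinical concentration–time curves span three orders of magnitude — from
the ~5 mg/L of an 81 mg antiplatelet dose to the >300 mg/L of mild
overdose — and no single dose level identifies the kinetics on its own.
`salclear` is for pharmacokinetic modellers who want to analyse such
dose-diverse progress curves *simultaneously* with one mechanistic model
and get honest uncertainty estimates back.

## Models

Three nested descriptions of dS/dt are implemented:

1. **First-order washout** — dS/dt = −k·S, with half-life
   t½ = ln 2 / k. Descriptive only: each dose level yields its own
   unrelated k.
2. **Briggs–Haldane / Michaelis–Menten** — dS/dt = −V·S/(K_m+S):
   zero-order (rate ≈ V) when S ≫ K_m, first-order (rate ≈ V/K_m·S)
   when S ≪ K_m. Solved from the exact implicit progress curve
   S + K_m·ln(S/S₀) = S₀ − V·t.
3. **Reversible enzyme scheme** — mass-action ODEs for
   S + E ⇌ SE → E + P with product rebinding
   (K_S = k_off1/k_on1, K_P = k_off2/k_on2, E = E_TOT − SE), integrated
   with a stiff solver. Effective constants follow as
   K_m = K_S + k_off2/k_on1 and V_max = k_off2·E_TOT.

Fitting minimizes the sum of squares of weighted residuals (SSWR) over
all dose groups at once, with per-curve weights equalizing each group's
contribution, a seeded multi-start Nelder–Mead simplex on log-scaled
parameters, Gauss–Newton covariance SDs, and Monte Carlo refits of
noise-perturbed replicates for empirical SDs. Since the original
clinical series were digitized from figures and never printed, the
package ships a synthetic-data module that generates the three-group
design from a chosen truth model, so every claim is testable end to end.

## Worked example

Generate the default three-dose scenario (reversible-enzyme truth, 1%
proportional noise) and refit it with the kinetic parameters free and
the initial concentrations fixed:

```python
from salclear.fitting import enzyme_condition_config, fit_model
from salclear.synthetic import DEFAULT_S0, default_scenario
from salclear.io import render_fit_report

data, record = default_scenario(seed=2015)
cfg = enzyme_condition_config(data, "C", s0_values=DEFAULT_S0, seed=0, n_starts=1)
print(render_fit_report(fit_model(data, cfg)))
```

```
model: enzyme   datasets: high, low, mid
converged: True   SSWR: 0.000287902   n_points: 27   n_free: 3

parameter         estimate          sd  how
KS                    10.4       0.156  Opt
KP                     275        13.2  Opt
koff2                 14.7       0.141  Opt
kon1                     3           -  Fixed
ETOT               0.00015           -  Fixed
S0_low                5.67           -  Fixed
S0_mid                64.9           -  Fixed
S0_high                335           -  Fixed
Km                    15.3           -  Calc
Vmax                  7.92           -  Calc
koff1                 31.1           -  Calc
kon2                0.0534           -  Calc

per-curve weight / fractional residual error:
  high     w=1.28419e-06  fre=0.01078
  low      w=0.0737926  fre=0.00741
  mid      w=4.73181e-05  fre=0.007416
```

The three optimized parameters recover the generating truth
(K_S = 10.44 mg/L, K_P = 273.5 mg/L, k_off2 = 14.82/s) to within about
1% for K_S and k_off2; K_P is looser because no product concentrations
are observed. The Calc rows translate them into the effective
Michaelis–Menten constants: K_m ≈ 15.3 mg/L and V_max ≈ 7.9 mg/(L·h),
i.e. a saturated (overdose) patient clears only ~8 mg/L of salicylate
per hour regardless of concentration. The per-curve fractional residual
errors sit at the 1% noise floor.

The same pipeline is scriptable from the shell:

```sh
salclear generate --seed 2015 --out-dir data/
salclear fit --config examples/fit_enzyme.yaml --out-dir out/ data/low.csv data/mid.csv data/high.csv
salclear montecarlo --config examples/montecarlo.yaml --out-dir mc/ data/*.csv
```

Annotated configuration examples live in `examples/`.

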