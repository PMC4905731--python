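# Methods

## The system being modelled

Salicylate (S) enters the body as aspirin, whose hydrolysis is fast
enough to treat absorption as instantaneous; the whole body is a single
well-mixed compartment. Clearance is dominated by enzymatic conversion
to salicylurate (P) — the rate-limiting step being a mitochondrial
acyl-CoA synthetase — so the model reduces to one enzyme acting on one
substrate, with the enzyme–substrate and enzyme–product complexes
treated as a single interconvertible species SE. The package implements
three nested models of dS/dt and the machinery to fit them to several
dose groups at once.

## Model equations and assumptions

**First-order washout.** dS/dt = −k·S, S(t) = S₀·e^{−kt},
t½ = 60·ln2/k minutes. Used as a per-group descriptive baseline; it has
no mechanism to share across dose levels.

**Michaelis–Menten (Briggs–Haldane).** dS/dt = −V_max·S/(K_m+S).
Rather than integrating, the package solves the exact implicit progress
curve S + K_m·ln(S/S₀) = S₀ − V_max·t per time point with a bracketed
scalar root finder (relative tolerance 1e-15). This is exact in both
regime limits, immune to stiffness, and an ODE integration of the same
rate law is kept as an independent cross-check in the tests.

**Reversible enzyme scheme.** Mass-action ODEs in canonical units
(mg/L, hours):

    dS/dt  = −kon1·S·E + koff1·SE
    dSE/dt =  kon1·S·E + kon2·P·E − (koff1+koff2)·SE
    dP/dt  = −kon2·P·E + koff2·SE − G·P,     E = ETOT − SE

with S(0)=S₀, SE(0)=0, P(0)=0. The kon2·P·E term in dSE/dt makes
S+SE+P exactly conserved when G = 0; a `strict_mass_balance` flag
removes it, reproducing a published equation set in which product
rebinding consumes P without forming complex (and therefore leaks mass
whenever kon2 > 0). The default is the conserving form. G, a first-order
consumption of P standing in for renal clearance, defaults to 0.

**Units.** Rate constants kon1, koff1, koff2, kon2 are entered per
second, as kinetics tables quote them, and converted once (×3600) at the
type boundary; derived velocities are mg/(L·h). The derived-parameter
identities are K_m = K_S + koff2/kon1, V_max = koff2·ETOT·3600,
koff1 = K_S·kon1, kon2 = koff2/K_P, and the equilibrium ratio
S/P = (koff1/koff2)·(K_S/K_P). The reversible uni-uni rate law
(net flux (V_f·S/K_s − V_r·P/K_p)/(1+S/K_s+P/K_p)) is provided for
cross-checking its zero-flux condition against the equilibrium ratio.

## Numerical choices

The enzyme scheme is stiff: at kon1 = 3 L/(mg·s) and ETOT = 1.5e-4 mg/L
the complex relaxes in well under a second while clearance takes hours.
The default integrator is LSODA with an analytic Jacobian, rtol 1e-8,
and absolute tolerances 1e-10 on S and P and 1e-12 on SE (which never
exceeds ETOT = 1.5e-4). Observation times are evaluated through the
solver's own continuous extension. Halving the tolerances changes S(t)
by far less than 0.01%, and BDF agrees with LSODA to the same level;
mass conservation holds to ~1e-15 relative in practice. A failed solve
raises, and a state more negative than solver-noise level raises;
negative excursions within noise are clipped to zero.

## Fitting

The objective is SSWR = Σ_c w_c Σ_i p_ci (obs−pred)², point weights
p = 1 by default. For simultaneous fits the per-curve weights are
equalized as w_c = 1/Σ_i obs_ci², making every group's weighted sum of
squared observations exactly 1 — without this the high-dose curve
(≈300 mg/L) would swamp the low-dose one (≈5 mg/L). Manual weights are
accepted, and the weights used in the original combined-dose analysis
(1.6435 / 0.0211 / 0.0034), whose derivation was never published, are
loadable as `REFERENCE_CURVE_WEIGHTS`.

Kinetic parameters are shared across groups; each group keeps its own
initial concentration `S0_<label>`. The standard enzyme masks are:
condition A, each group fitted alone; B, simultaneous with free S0s; C,
simultaneous with S0s fixed (kon1 and ETOT are always fixed — without
early-time or product data they are unidentifiable, ETOT entering only
through ETOT·koff2).

The optimizer is Nelder–Mead on log-transformed parameters (all are
positive and span decades), with N = 5 jittered restarts (log-space
Gaussian jitter, SD 0.2, seeded) and explicit bounds, when given,
enforced by a logistic transform. Ties at equal SSWR break to the
smallest log-space L2 norm, deterministically. Starting values are
bootstrapped from the data: V_max from the two-point slope of the
highest-dose curve, V_max/K_m from the end-point log-slope of the
lowest-dose curve, enzyme affinities from the resulting Michaelis
constants with K_P started at 10·K_m. Datasets are sorted by label
internally, so results are invariant to input order.

Parameter SDs come from the Gauss–Newton approximation: with weighted
residual Jacobian J (central differences, relative step 1e-4),
cov = s²(JᵀJ)⁻¹, s² = SSWR/(N−p). A rank-deficient Jacobian (or N ≤ p)
reports SDs as NaN rather than inventing numbers; the correlation
matrix is returned alongside (ETOT and koff2, if both freed, correlate
at r ≈ 0.8, which is why ETOT stays fixed).

## Monte Carlo uncertainty

`monte_carlo_refit` perturbs every observation independently by a
multiplicative U(−f, +f) factor (default f = 0.01; the proportional
reading is forced by the 300-fold concentration range — additive noise
of any single scale would be absurd at one end or the other), refits,
and reports empirical means and SDs over accepted replicates.
Replicates restart the simplex from the baseline optimum for speed; a
from-scratch mode exists for bias checks. Replicates with K_S, K_P or
k_off2 above 1000 (in mg/L resp. 1/s) are rejected as runaway fits; on
well-specified synthetic data the rejection rate is far below 5%. With
f = 0 the perturbed data equal the original, so replicates are returned
as copies of the baseline (SDs exactly 0). `gaussian_ratio_sd` samples
independent Gaussians for a numerator and denominator (e.g. V_max/K_m
from their individual means and SDs) and returns the empirical SD of
the ratio, agreeing with the delta method when the denominator spread
is small.

## Synthetic data

The generator emulates the published three-group design: low dose
(7 points, 1.9–12 h, S₀ = 5.67 mg/L), mid dose (11 points, 0.75–13 h,
S₀ = 64.9 mg/L), high dose (9 points, 0.95–15.94 h, S₀ = 335 mg/L),
log-spaced within each window. The exact published sampling times are
unavailable (the originals were digitized from figures), so the grids
are representative, not replicas. The reference truth is the reversible
enzyme scheme at K_S = 10.44 mg/L, K_P = 273.5 mg/L, k_off2 = 14.82/s,
kon1 = 3 L/(mg·s), ETOT = 1.5e-4 mg/L, G = 0. Group noise is
multiplicative: Gaussian with 2% CV by default as a realistic assay
model, or uniform half-width to mirror the Monte Carlo perturbation
exactly; `default_scenario` uses 1% with a fixed seed (2015) and derives
per-group child seeds from a SeedSequence. What passing recovery tests
on these data show is that the *estimation machinery* is unbiased and
well-conditioned under the stated design; they cannot certify the
biology of the real averaged clinical curves, which carry population
averaging, assay drift and absorption-phase effects the generator does
not emulate.

## Scale of the shipped experiments

The recovery experiment fits condition C on 20 independently seeded
scenarios (single-start fits, since the bootstrap start is close and
the optimum is unique in practice); the Monte Carlo check runs 200
replicates, a 5× reduction from the reference analysis's 1000 chosen to
keep the routine suite quick while leaving the SD/mean estimate's own
error near 5%. Both finish in minutes on one core.

## Known limitations and open choices

- The zero-order "limit" of the M-M model is only asymptotic: the exact
  deviation from the line S₀ − V_max·t is K_m·ln(S₀/S), i.e. 23% of S
  already at S = 10·K_m (S₀ = 100·K_m). Limit checks therefore assert
  the 1% band over the deeply saturated stretch S ≳ 0.6·S₀, where the
  same closed form guarantees it.
- K_P (hence kon2 and the equilibrium S/P ratio) is weakly identified
  without product measurements: only the flattening of the low-dose
  tail constrains it. Recovery tolerances reflect that.
- SE and PE are one species; pH/ionization, plasma-protein binding,
  transport into mitochondria, and multi-compartment variants are out
  of scope, as are subject-level covariates (the data the design
  emulates are population averages).
- Model comparison is by SSWR and residual structure only; no
  information criteria are computed.
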