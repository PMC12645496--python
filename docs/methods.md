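# Methods

## The model

`gcthybrid` implements a deterministic ODE model of granulosa cell
tumor (GCT) therapy with a TRAIL-producing oncolytic virus combined
with oral PAC-1, and couples its per-patient solutions to a
machine-learning evaluation layer.

**Tumor cell cycle.** Quiescent cells Q enter G1 at rate a1; G1 cells
either die (rate d2, amplified by the drug effect, see below) or enter
a chain of j = 6 identical transit compartments A1..Aj at rate a2.
Transit at rate ktr gives the active phase an Erlang-distributed
duration with mean tau = j/ktr ≈ 0.71 days; cells leaving Aj divide,
returning 2·ktr·Aj cells to Q. Active-phase cells die at d3(1+E).
Tumor pools are expressed in scaled units of 1e10 cells.

**Oncolytic virus.** Free virions V infect cycling cells (G1 plus the
active pool N = ΣA_i) at the saturating per-cell hazard
κ·V/(η_half + V); infected cells I lyse at δ, releasing α virions each;
free virions decay at ω.

**Innate immunity.** Infected cells drive cytokine production from the
homeostatic rate Cprod\* up to Cprod_max with half-effect ψ_half;
cytokine C recruits phagocytes P at φ(C) = kcp·C/(C_half + C); P kills
tumor cells at kp·P with saturable handling (1 + kQ·Q for quiescent,
1 + ks·G1 for cycling cells). The infection-free equilibrium is
C\* = Cprod\*/k_elim ≈ 2.47e-3 ng/ml and P\* = φ(C\*)/γP ≈ 4.45e-2
scaled units.

**PAC-1 pharmacokinetics.** Oral doses enter a gut depot PA (ng),
absorb at ka into plasma (concentration P_PAC over volume V_PAC), with
two-compartment distribution (k12P, k21P) and elimination kep.

**TRAIL pharmacokinetics.** Irreversible target-mediated drug
disposition: free TRAIL T binds a constant receptor pool R0 at kon;
the complex TP internalizes at kint; T also exchanges with a peripheral
amount TA (k12, k21, central volume V), is eliminated at kel, is
produced at αT·δ·I by lysis, and at a constant rate Tprod. Tprod is not
tabulated anywhere; we derive it so that the drug-free, tumor-free
subsystem is in equilibrium at the homeostatic concentration
T\* = 0.08090 ng/ml:

    TP* = kon·R0·T*/(kint + kon·T*),   Tprod = kel·T* + kon·T*·(R0 − TP*)

giving Tprod ≈ 4.603 ng/ml/day. A 100-day simulation holds C, P and T
within 0.5% of these equilibria (acceptance check).

**Pharmacodynamics.** Each drug contributes a Hill term
E_x = Emax_x·c^γx/(EC50_x^γx + c^γx). The combined effect is, by
default,

    E = E_P + E_T + Ψ·E_P·E_T

with the potency Ψ = 0.8 as interaction weight; Bliss independence and
a PAC-1-only variant are selectable. E multiplies the apoptotic rates
as d2(1+E) and d3(1+E), bounded by 1.62 at saturation.

### Structural variants

The published form of this model family contains several internally
inconsistent terms; `ModelConfig` makes each resolution explicit and
keeps the literal readings behind flags:

* infection target (G1 − N) would drive infected cells negative; the
  default uses (G1 + N), consistent with infection of "G1 and active
  phase" cells (`corrected_plus` vs `literal_minus`);
* entry into A1 at a1·G1 conflicts with the stated a2 progression rate;
  default a2·G1 (`text_a2` vs `literal_a1`);
* the separate equation for the total active pool N is redundant (it is
  the exact sum of the transit-chain equations); by default N ≡ ΣA_i is
  algebraic (`algebraic_sum` vs `ode_eq5`);
* a (kep − k12P) elimination term would be negative with the fitted PK
  values (61.97 − 183.49); the standard mass balance (kep + k12P) is
  used;
* oral absorption is ka·PA/V_PAC (amount over volume of distribution),
  and the TRAIL peripheral exchange is −k12·T + k21·TA/V paired with
  dTA/dt = k12·V·T − k21·TA so the transfer conserves amount;
* the TMDD complex equation uses the standard irreversible form
  kon·(R0 − TP)·T − kint·TP.

`clip_negative` (default on) projects the state onto the nonnegative
orthant before evaluating the right-hand side; with the corrected
variants the vector field is already nonnegativity-preserving, but the
literal variants can cross zero.

## Simulation

Dosing is impulsive: 375 mg → 3.75e8 ng added to PA once daily; the
viral inoculum MOI × tumor cells is deposited at t = 0 (0.03 × 1e9
cells = 0.003 scaled virion units). Integration restarts at each dose
event. The default integrator is adaptive explicit Runge–Kutta 4(5)
with rtol 1e-6, atol 1e-9; a fixed-step classical RK4 (dt configurable,
1e-4 days in the solver cross-check) is available as an independent
numerical oracle — the two agree on the day-21 burden of the baseline
protocol to better than 1e-3 relative.

Independent patients are stacked into one vectorized system
(`simulate_batch`) so cohort-scale work (500 trajectories) completes in
seconds; batch and single-patient solves agree to solver tolerance.

Initial tumor mass is split across compartments either all-quiescent or
(default) proportionally to mean residence times 1/a1, 1/(a2+d2) and
j/ktr; immune, cytokine and TRAIL variables start at their analytic
equilibria. Conversions: 1e10 cells per scaled unit, 1e9 cells per cc
of tumor volume.

## Dynamical regime, and the choice of cohort time grids

With the default parameters the model is bistable: the immune
equilibrium kills at ≈ 0.41/day against a net cycling gain of
≈ 0.29/day, so tumors below roughly 150 cc are cleared over a few
weeks, while larger ones escape immune control. Under the baseline
protocol (21 daily 375 mg doses, MOI 0.03) clearance accelerates
sharply with baseline size — more cycling targets mean more virus,
TRAIL and drug-amplified apoptosis. Consequences:

* every plausible clinical baseline (1–60 cc) regresses during therapy;
  "final volume" contrasts between parameter settings are exponential
  amplifications of net-rate changes;
* imaging time points must lie inside the treatment course to record
  informative volumes. The synthetic cohorts therefore default to MRI
  at {0, 7, 14, 21} days (4-point) or {0, 10, 21} days (3-point). At
  the 2–6 month spacings typical of surveillance imaging the modeled
  tumors are already cleared and every measurement would be degenerate.

## Synthetic cohorts

The generator emulates the *schema* of observational GCT/ovarian-cancer
tables, not any real registry's distributions. Defaults: age ~
N(55, 12) truncated to [18, 90]; BMI ~ N(27, 5) truncated to [15, 50];
marginal prevalences BRCA 0.10, TP53 0.20, PIK3CA 0.15, lymph-node
positivity 0.30; three ethnicity codes (0.7/0.2/0.1); baseline volume
log-normal (median 8 cc, sd 0.5 log units); multiplicative log-normal
measurement noise with sd 0.1 log units; volumes floored at one cell
(1e-9 cc). Covariates act on the mechanism through multiplicative
parameter effects (lymph-node+ → a1×1.2, BRCA → d2×1.15, TP53 →
d2×0.9, PIK3CA → a2×1.1), so the generated tables contain exactly the
mechanistic signal the enrichment step is supposed to expose. A hidden
truth table stores each patient's parameters and pre-noise volumes;
re-simulating from it reproduces the recorded volumes to solver
tolerance (tested).

Categorical cohorts tertile-code the final observed volume into
SizeCategory ∈ {1, 2, 3} (ties to the lower bin; a constant vector is
all category 1) and keep the latent volumes in the truth table.

What passing tests on these cohorts do *not* show: anything about real
GCT registries (none are publicly deposited), about imaging error
structure beyond i.i.d. log-normal noise, or about covariate effects
that bypass the modeled mechanism.

## Enrichment

Continuous cohorts: each patient's trajectory is simulated from their
observed Volume1 under the shared treatment schedule with the *base*
parameter set (enrichment does not see the hidden per-patient
parameters), and the default feature set — total burden (cc), infected
cells, virions, cytokine, phagocytes, plasma PAC-1, free TRAIL — is
sampled at {7, 14, 21} days and appended as `model_<var>_t<t>` columns.
Failed simulations leave NaN features and a `model_sim_failed` flag;
patients are never silently dropped.

Categorical cohorts: each tertile group receives one shared
Uniform(0, 100) cc initial volume (a per-patient draw is available by
flag), and every appended feature column is itself tertile-coded.

## ML evaluation

Regression: OLS with intercept (statsmodels); the reported RMSE is
5-fold cross-validated (shuffled folds, seeded) with the in-sample RMSE
(divisor n) also reported; coefficient p-values are two-sided t-tests,
the overall p an F-test; "significant" means p ≤ 0.05 (configurable).
Collinear columns are dropped rightmost-first with a warning.

Classification: a single-hidden-layer MLP with 50 units
(scikit-learn, early stopping off, max_iter 300), repeated over
independent stratified 70/30 splits (default 100 repetitions);
confusion-matrix metrics are macro-averaged over classes, then averaged
over repetitions (micro available). A class with zero support or zero
predictions scores 0 on the undefined metric, with a warning.

Comparisons always evaluate both arms (clinical only vs clinical +
model features) on *identical* splits by sharing fold/repetition seeds.
On default synthetic cohorts (n = 500), the cross-validated RMSE for
predicting the second MRI volume is lower with model features in
≥ 8/10 generator seeds, and the repeated-NN accuracy does not drop —
the directional enrichment benefit, on data where the mechanism is true
by construction. The benefit is driven by the strong nonlinearity of
the treated growth map V1 → V2; a generator configured with untreated
natural history yields a nearly log-linear map whose curvature is too
small relative to 10% measurement noise for a consistent regression
improvement.

## Sensitivity analysis

One-at-a-time: each parameter scaled by 1+f for 9 fractions f in
[−0.85, 0.85] (endpoints from the protocol definition; the grid density
is ours), re-simulating the baseline protocol; influence = max over the
grid of |burden(f) − burden(0)|/burden(0) at day 21, ranked descending
with alphabetical tie-break. The integer compartment count j is
excluded (fractional scaling is ill-defined), as are the bounded
efficacies Emax_PAC/Emax_TRAIL/Ψ (a +85% scaling leaves their
admissible range) and the unit conventions.

**Known limitation / negative result.** With the published parameter
values the sweep is dominated by the immune-control parameters: kp and
kcp (influence ≈ 2e4, from the −85% endpoint at which immune kill
collapses and the tumor escapes), then Cprod\*, C_half, γP, k_elim.
The cell-cycle pair often cited as most influential for this model
family ranks lower here: d2 around rank 12 (influence ≈ 5.8) and a1
around rank 22 (influence ≈ 0.5 — at a1 = 3.35/day quiescence exit is
not rate-limiting, so ±85% barely moves the net growth rate). The
corresponding acceptance check asserts the cited ranking and fails on
this implementation; the ranking itself is stable under grid doubling
and across solver tolerances.

## Parameter recovery

`calibration.fit_parameters` refits (a1, d2) by trust-region least
squares on log-volume residuals, in log-parameter space, from 20
simulated series (baselines log-spaced 1–30 cc, observations at
{3.5, 7, 10.5, 14} days under daily dosing). The treated design is
deliberately chosen: the drug effect modulates d2(1+E) in time and the
virus couples kill to burden, which breaks the near-collinearity of a1
and d2 that an untreated exponential design would suffer. Noise-free
data recover both within 0.02%; with 5% log-normal observation noise
the median error over 10 seeds stays below 1%.

## Numerical choices and degenerate inputs

* solver tolerances rtol 1e-6 / atol 1e-9 (halving changes day-21
  burden < 0.1%, tested);
* tertile boundaries at the empirical 33.33%/66.67% quantiles, ties to
  the lower bin;
* recorded volumes floored at one cell (1e-9 cc) before noise;
* log-residual floor 1e-30 cc in calibration;
* zero-horizon simulations return the initial state; zero-tumor states
  are exactly invariant for the tumor subsystem;
* all stochastic procedures consume a single seeded NumPy generator per
  stage and are bit-reproducible (the full CLI pipeline rerun is
  byte-identical, tested).

## Problem sizes used in the shipped checks

Acceptance-level checks run at: 1000 random states for the RHS oracle;
100-day homeostasis; 21-day protocol for the solver cross-check
(RK4 dt = 1e-4); the full 38-parameter sweep at 9 and 17 grid points;
20-series recovery with 1 noise-free + 10 noisy fits; 10 cohorts of
n = 500 for the regression comparison and 100 NN repetitions on one of
them; 200–500 null replicates for the statistical calibration; and an
n = 80 pipeline for the byte-identity check. These sizes are the
package's own desk-scale choices; all are configurable upward.
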