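# Methods

## Structural and covariate model

Vancomycin disposition is described by a two-compartment model with
zero-order intravenous infusion input and first-order elimination
(micro-constants k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp). Concentration–time
profiles are the closed-form superposition over dose events of the
single-infusion solution in the two macro rate constants (roots of
λ² − (k10+k12+k21)λ + k10·k21 = 0); the solution is continuous at the end of
infusion and linear in dose. The roots can only coincide in the limit
Q → 0 with k10 = k21; a relative floor of 1e−12 on the discriminant keeps
them separated, which reproduces the one-compartment limit rather than
dividing by zero. The analytic solution is checked against a stiff LSODA
integration of the mass-balance ODEs (relative error below 1e−6 over 100
random parameter/dose draws).

Clearance carries three covariate effects: allometric body weight with the
exponent fixed at 0.75 (0.75 for clearances, 1.0 for the central volume;
neither is estimated), serum albumin as an inverse power term
(29/ALB)^α — hypoalbuminemia raises the unbound fraction available for
convective removal, so α > 0 raises CL below the 29 g/L reference — and the
ultrafiltration rate as an additive term UFR·β representing extracorporeal
convective clearance. A single log-normal random effect η multiplies the
whole clearance expression; volumes and Q carry no between-subject
variability. Units are fixed throughout (h, mg, L, mg/L, g/L, mL/kg/h).

Although vancomycin input is sometimes loosely described as "absorption",
the drug is given intravenously; the model input is a zero-order infusion,
with a default duration of 1.0 h (standard practice) overridable per dose
event and per regimen.

## Estimation (FOCE-I)

With one random effect the marginal likelihood per subject is a 1-D
integral. Writing l(η) = −2 log[p(y|η) p(η)], the objective contribution is
the Laplace-type expansion at the conditional mode η̂ (the empirical Bayes
estimate),

    OFV_i = l(η̂) + log(l''(η̂)/2) − log 2π,

with the residual variance evaluated at the conditional (individual)
prediction — the "interaction" term. The population OFV (an approximation of
−2 log marginal likelihood, constants included) is additive over subjects
and is verified against adaptive Gauss–Hermite quadrature (61 nodes) to
better than 0.5% on small studies for all four residual models: additive,
proportional, combined (two variance components σ², σ'²) and exponential
(fitted as additive on log-concentrations). When ω² < 1e−10 the random
effect is pinned at zero and the OFV reduces to the fixed-effects −2 log
likelihood exactly.

Numerical choices:

* **Inner problem.** η̂ is found by a safeguarded Newton iteration (central
  differences with step 1e−4, steps damped to |Δη| ≤ 1, stop at
  |Δη| < 1e−8), warm-started from the previous outer iteration; it falls
  back to a vectorized bracketing grid plus Brent (xtol 1e−8, documented
  start 0, search bounded to |η| ≤ 10) whenever the curvature is
  nonpositive. The same curvature supplies l'' for the Laplace term, with
  2/ω² as a floor. The public `conditional_eta` uses start 0 and matches an
  exhaustive grid search to 1e−4.
* **Outer problem.** Nelder–Mead on transformed parameters —
  log-transformed clearances, volumes and variances (positivity), raw
  covariate exponents and slopes — with a custom initial simplex (step 0.25
  on log parameters, 0.5 on exponents, and for additive slopes the step
  that shifts a typical clearance by 15% at the mean covariate value).
  Function tolerance 1e−6 on the OFV; parameter sets yielding a nonpositive
  typical clearance are rejected with a large penalty. Default starting
  values are order-of-magnitude adult values (CL 1.2 L/h, Vc 15 L, Vp 25 L,
  Q 7 L/h, covariate effects 0, ω² 0.1, σ² 0.05). Fits are deterministic
  given data, initial values and tolerances; a verification restart from a
  converged optimum reproduces the same OFV and estimates, so a single run
  is performed. Pre-dose observations (model prediction identically zero)
  are excluded from the likelihood and counted in the result.
* **Standard errors.** The covariance matrix is the inverse of one half of
  the central finite-difference Hessian of the OFV at the optimum (relative
  step 1e−3); %RSE = SE/estimate × 100, reported for variance terms as the
  %RSE of the variance estimate. A non-positive-definite Hessian yields NaN
  with a warning, never fabricated values.
* **Diagnostics.** PRED is the prediction at η = 0, IPRED at the subject's
  empirical Bayes η̂, and CWRES the conditional weighted residual: the
  observation minus the η̂-linearized conditional mean, scaled by the
  inverse Cholesky factor of F ω² Fᵀ + diag(g) with the residual variance g
  evaluated at IPRED. With a multiplicative error model and a zero
  prediction the residual is undefined and flagged.

AIC = OFV + 2·(number of estimated parameters) compares structural
candidates (one- vs two-compartment).

## Covariate selection

Pre-screening is advisory: pairwise association among covariate columns
using Pearson's correlation when both columns pass Shapiro–Wilk normality,
Kendall's τ otherwise, and a two-sample t-test for discrete-vs-continuous
pairs; pairs with p < 0.05 are flagged for the analyst. Which member of a
correlated pair to keep is a configuration decision, not an algorithm.

Stepwise selection on the OFV: forward inclusion admits, one candidate at a
time, the largest OFV drop provided it strictly exceeds 3.84 (χ²(1),
p < 0.05; exact ties broken by candidate list order); backward elimination
retains a covariate only if its removal raises the OFV by more than 10.83
(p < 0.001); finally a retained covariate whose effect-parameter 95% Wald CI
includes zero is removed. Allometric weight is part of the base model and
never tested. Candidate functional forms are power, inverse-power (the
albumin form, so the reported exponent keeps its conventional sign) and
additive (the UFR form). Candidate fits start from the current model's
estimates with the new effect at zero; non-converged candidates are skipped
for that step and logged. Under a null generating model the per-candidate
false-inclusion rate tracks the χ²(1) 5% tail (checked over 100 simulated
replicates).

## Model evaluation

**Bootstrap.** Subjects are resampled with replacement (same n), each
replicate refitted starting from the final estimates (which speeds
convergence); failed replicates are excluded and counted. Per-parameter
medians and 2.5–97.5 percentile CIs are reported. Default B = 2000; the test
suite uses B ≤ 20 for runtime.

**Numerical predictive check.** n_sim replicate datasets are simulated under
the fitted model (same design and covariates, fresh η and ε); for each
observation and level L ∈ {0, 20, 40, 50, 60, 80, 90, 95} the prediction
interval is the ((100−L)/2, (100+L)/2) percentile band of its simulated
values (level 0 is the median split). Real observations below/above their
bands are counted; the 95% CI of each count is the 2.5–97.5 percentile of
the same count computed replicate-wise, treating each simulated dataset as
pseudo-observed (the standard NPC construction; an analytic CI would be an
alternative). Default n_sim = 1000 (warning below 100); the test suite uses
400. Self-simulation calibration: ~10% of observations fall outside the 90%
band, within binomial tolerance.

## Dose optimization by PTA

Virtual subpopulations are defined by albumin band (low 15–34, normal
35–55 g/L) × ultrafiltration bin ([20,25), [25,30), [30,35), [35,40]
mL/kg/h). Covariates are sampled independently within a subgroup: albumin
and UFR uniform in their band/bin, weight truncated log-normal (median
70 kg, log-SD 0.24, bounds [52, 90] kg), η ~ N(0, ω²) fresh per virtual
patient. AUC24 is evaluated at steady state as daily dose / CL — exact under
linear PK and independent of the assessment day, matching guideline
practice; residual (assay) error is excluded since it does not change a
patient's true exposure. PTA per regimen is the fraction of n = 10,000
virtual patients inside the target window. The decision window is
400–650 mg·h/L with 400–600 always co-reported.

Because steady-state AUC24 depends on a regimen only through its daily
dose, regimens with equal daily dose tie exactly; ties are broken by fewest
daily administrations, then lowest total daily dose. The default grid
therefore spans the per-administration doses used clinically in this
setting — 5 and 10 mg/kg at qd/q12h/q8h with 1-h infusions — and is
configuration-extensible; a denser grid (e.g. adding 7.5 or 15 mg/kg)
introduces equal-daily-dose aliases of the divided regimens that the
tie-break would collapse onto once-daily dosing.

## Synthetic-study generator

The generator emulates the source trial design: n subjects (default 11),
0.5 g infusions assigned per subject from a qd/q12h/q8h pool, samples at
baseline and 0.5, 1, 2, 4, 6, 8, 10, 12 h after the first dose with the
schedule repeated on day 3 under uninterrupted dosing. The day-1 baseline is
pre-dose (zero); the day-3 baseline is a trough. Covariates come from
truncated distributions matching the cohort's published medians and ranges:
weight log-normal (median 70 kg, log-SD 0.24 from the published IQR,
truncated [52, 90]), albumin normal (28.6 g/L, SD 3.8, truncated [26, 39]),
UFR normal (33.3, SD 4.8, truncated [18, 39]). Truncation at the published
range slightly shrinks the realized IQRs and shifts the albumin median up
(~1 g/L); matching the published IQRs exactly inside the published ranges
is infeasible (the weight IQR of 22.5 kg exceeds the maximum attainable
inside [52, 90]), so the simple median-matched forms are kept. An optional
per-sample dropout probability emulates the missingness implied by 131
observations from a nominal 11 × 18 schedule (the anchor baseline is never
dropped). Not simulated: CVVH circuit downtime or filter changes,
within-subject covariate drift, assay LLOQ censoring, and any correlation
between covariates.

## What the synthetic studies do and do not show

Passing the recovery and calibration tests demonstrates the estimator,
selection, evaluation and simulation machinery are internally consistent
under the stated design — not that real CVVH data obey the model. Two
limitations matter when comparing with the source cohort:

* **Weak identifiability of the clearance decomposition.** At the reference
  design (100 subjects, all on 500 mg q12h, covariates as above), the
  clearance covariate decomposition is intrinsically soft: sampling SDs are
  roughly 26% for CL_pop, 35% for α, 22% for β and 16% for ω², while Vc,
  Vp, Q and σ² are sharp (2–4%). The estimates are unbiased, and the
  clearance *function* CL(WT, ALB, UFR) is well identified (typical CL at
  the median covariates recovers within a few percent), but any single
  recovered value of CL_pop, α or β can sit tens of percent from its
  generating value on a given seed. This is a property of the design, not
  of the optimizer: restarts reproduce the same optimum, and the
  finite-difference Hessian agrees with an independent nonlinear-regression
  Monte Carlo of the same problem.
* **Covariate independence in the PTA populations.** Real CVVH cohorts show
  a negative weight–UFR association (per-kg ultrafiltration prescriptions
  run higher in lighter patients). With covariates sampled independently,
  the PTA table reproduces the expected recommendation in six of the eight
  subgroup bins; in the normal-albumin/UFR 35–40 bin (where lighter
  patients would lower AUC24 and favor the higher daily dose) and the
  marginal low-albumin/UFR 25–30 bin it selects the adjacent daily dose.
  Joint covariate sampling would be needed to probe this and is out of
  scope here.

## Problem sizes used by the packaged checks

The test suite and the reproduction script size their simulations as the
package's reference configurations: one 100-subject study for parameter
recovery; 2-subject toys for quadrature oracles; 100 replicates of a
10-subject one-compartment study for stepwise calibration; a 40-subject
study with 400 simulations for NPC calibration; 10,000 virtual patients per
subgroup (10 seeds) for the recommendation table; bootstrap examples at
B ≤ 20.
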