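# Methods

`leanbone` implements a longitudinal path analysis of paired muscle and
bone measures — DXA lean mass (LM, kg) and areal BMD (g/cm²) at the legs,
arms, and both appendicular sites — observed at three visits (V0, V3, V5;
nominally 0, 48 and 120 months). This note records the models, the
numerical choices, and what the synthetic generator does and does not
emulate.

## The cross-lagged panel model

For one region, muscle M and bone B at the three visits form six observed
endogenous variables. The canonical structure has

- **contemporaneous** muscle→bone paths within each visit (3 free
  coefficients, `beta_mb_v0/v3/v5`),
- **cross-lagged** paths in both directions across each lag
  (`gamma_mb_lag1/lag2`, `gamma_bm_lag1/lag2`),
- **autoregressive** paths per construct, equality-constrained across the
  two lags by a shared parameter label (`rho_muscle`, `rho_bone`), and
- one free disturbance variance per endogenous variable.

Baseline covariates (age, height, weight, smoking, alcohol, diabetes,
walking, grip strength, arthritis, prior fracture after 40,
hospitalization) enter as an exogenous block: freely intercovarying, each
with a directed path to all six endogenous variables. Only the covariance
structure is modelled; means are saturated. The within-visit muscle→bone
direction is a modelling convention — contemporaneous association cannot
identify direction, which is precisely what the mediation and sensitivity
analyses probe.

The model is expressed in RAM form: with A the directed-coefficient matrix
and S the variance/covariance matrix, the implied covariance is
Σ(θ) = (I−A)⁻¹ S (I−A)⁻ᵀ. Fitting minimises the normal-theory maximum
likelihood discrepancy

F(θ) = log|Σ| + tr(S_sample Σ⁻¹) − log|S_sample| − p,

with the sample covariance computed with the N−1 denominator and the test
statistic χ² = (N−1)·F (Wishart convention; a switch selects N·F). Degrees
of freedom are p(p+1)/2 minus the number of distinct free labels — 6 for
the endogenous block. Freeing the V3 muscle↔bone disturbance covariance
(`free_v3_disturbance_cov=True`) gives the df = 5 variant; both are
exposed, neither is silently substituted for the other.

**Optimization.** Parameters are rescaled by their natural moment
magnitudes (variances by the sample variance, directed coefficients by the
target/source SD ratio) before optimization; this conditioning matters
once the covariate block brings the parameter count to ~150. The primary
run is BFGS with an analytic gradient
(∂F = tr[Σ⁻¹(Σ−S)Σ⁻¹ ∂Σ], assembled from the RAM structure). If it fails
to converge, quasi-Newton restarts with an enlarged evaluation budget are
applied (restarting resets the curvature model, which recovers from
line-search breakdowns); the optimizer used and whether the fallback ran
are recorded in `convergence_`. A final Newton polish against a
finite-difference Hessian takes the solution to near machine precision, so
closed-form equivalences (single-edge fits equal least-squares slopes;
saturated models give F = 0 exactly) hold to 1e-8. A non-positive-definite
Σ during search returns a smooth penalty value rather than an exception.
Starting values: autoregressive labels at 0.8, other directed coefficients
at 0, variances/covariances at sample moments.

**Uncertainty.** Parameter covariance is 2/(N−1) times the inverse
observed information (finite-difference Hessian of F at the optimum);
p-values use the normal reference. Standardized coefficients multiply each
directed coefficient by implied SD(source)/SD(target) — so two edges
sharing an equality-constrained label generally standardize differently —
with delta-method SEs propagated through a numerical Jacobian of the
standardization map.

## Fit assessment

χ² test of exact fit; SRMR over the p(p+1)/2 unique correlation-scale
residuals; RMSEA √(max(χ²−df,0)/(df·(N−1))) with a 90% interval obtained
by inverting the noncentral-χ² CDF in its noncentrality parameter
(root-finding to 1e-8; bounds pinned at the boundary report 0); and the
Bentler–Bonett NFI against an independence model (diagonal Σ, variances
free, covariate block included) fitted by the same engine. Adequacy uses
the two-of-four rule: χ² p > 0.05, RMSEA upper bound < 0.08, SRMR < 0.05,
NFI > 0.95; adequate iff at least two hold. The 90% level for the RMSEA
interval is the conventional default.

## Mediation decomposition

For a cross-lagged pairing (e.g. V0 muscle → V3 bone) the direct effect is
the direct edge coefficient and the indirect effect sums coefficient
products over every other directed route, enumerated exhaustively on the
acyclic graph. The canonical one-lag case is dominated by the two parallel
routes — through muscle persistence (V0 M → V3 M → V3 B) and through
contemporaneous-then-persistent bone (V0 M → V0 B → V3 B) — plus a
third-order route through both mediators whose product is negligible.
Totals satisfy direct + indirect exactly. SEs for composite effects use
the first-order delta method on the joint parameter covariance (a
bootstrap cross-check in the test suite agrees within 15%). Reporting
follows the conventional table layout: percent of total for direct and
indirect, and the |indirect|/|direct| ratio; a derived cell whose
denominator is below 0.01 standardized units is flagged "Div by 0" rather
than reported — a reporting convention reverse-read from typical published
flagging, configurable per call.

## Descriptives

Per-visit means/SDs with contrasts against baseline from a random-intercept
linear model (visit categorical); with balanced complete cases this is the
standard repeated-measures adjustment. Percent change is the **mean of
per-participant ratios**, not the ratio of visit means — the two differ
whenever change correlates with baseline, and the per-participant version
is what the reported decline figures are consistent with. Annualization
divides by the nominal window in years (120 months → /10). LMS z-scores
use z = ((X/M)^L − 1)/(L·S) with the log-limit form ln(X/M)/S below
|L| < 1e-8; the transform is strictly increasing and rejects X ≤ 0.

## Sensitivity analyses

`change_model` regresses an outcome change score over a window on a
predictor plus covariates, optionally adjusting for the outcome's
start-of-window value; 95% CIs are Wald intervals from least-squares SEs.
Rank-deficient designs raise a collinearity error naming the aliased
columns. `validate_constraints` reports the raw lag-1 autocorrelations of
each repeated measure against the 0.90 (0.80 fallback) thresholds used to
justify the equality constraints.

**Induced-association demonstration.** With the V3→V5 muscle→bone
cross-lag set exactly to zero and contemporaneous effects positive, a
change-score regression of bone change (V3→V5) on *V3-timed* muscle picks
up a spurious association of size ≈ β·ρ_m (propagation through the V5
contemporaneous path), while the *V0-timed* predictor's coefficient decays
with the square of the muscle lag correlation. Both population
coefficients have closed forms from the generative covariance (linear
projection of B5−B3 onto the predictor block), which the experiment
reports alongside the estimates. The default scenario uses deliberately
low muscle persistence (ρ_m = 0.15), the regime the demonstration targets:
a predictor measured years before the change window retains almost no
unique variance, so the baseline-timed model is genuinely null while the
same-time-point model is strongly "significant" despite a zero true lagged
effect. With cohort-level persistence (ρ_m ≈ 0.9) both predictors inherit
part of the induced association and the contrast is one of degree, not of
kind — worth remembering when reading real-data versions of this check.

## Synthetic cohort generator

The generator draws exactly the linear-Gaussian structure the model
assumes, per limb and side: visit intercepts, centred covariate effects,
the structural coefficients above, and independent homoscedastic
disturbances (a Student-t alternative with matched variance is available
for robustness runs). Default targets are calibrated to the scale of a
large cohort of Afro-Caribbean men followed over ten years: leg LM
10.58/10.42/9.77 kg (SD ≈ 1.5), arm LM 4.38/4.33/4.05 kg, leg BMD
1.403/1.381/1.390 g/cm², arm BMD 0.920/0.912/0.903 g/cm² across the three
visits; unstandardized defaults β ≈ 0.032 g/cm² per kg (leg, V0),
cross-lags of order 0.01, muscle autoregression 0.92 (leg) / 0.76 (arm)
and bone autoregression ≈ 1.03. Covariates: age as a truncated normal
(support ≥ 40, re-located so the post-truncation mean is 53; SD after
truncation ≈ 7.5), height N(175.4, 6.8²) cm, BMI truncated normal with
mean 27.43, binary prevalences (smoking 0.24, diabetes 0.18, arthritis
0.15, fracture 0.04, hospitalization 0.10, glucocorticoid ≈ 1/1286).
Distributions for alcohol (exponential, mean 4 units/week), walking
(gamma, mean 120 min/week) and grip strength (truncated normal, 42 ± 8 kg)
are invented defaults — no reference source specifies them — and are
flagged as such here and in the config docs.

Intercepts and baseline disturbance SDs are solved analytically so V0
means/SDs match the configured targets exactly in expectation; later-visit
disturbance SDs are solved against the target SDs given the structural
variance already implied. Because the default bone autoregression exceeds
one while the target SDs are nearly constant across visits, the implied
structural variance at V3/V5 can exceed the target; the solver then floors
the disturbance SD at 10% of the target SD and the realized SD sits
slightly above the nominal one. Left and right limbs are correlated
replicates (disturbance correlation 0.95; the right side exists to
exercise the side-selection rule). Dropout is
missing-completely-at-random per visit and side-exclusion
(prosthesis/fracture) flags persist once set; both are applied last.

What the generator does **not** emulate: informative dropout (the analyses
are complete-case), measurement drift or device effects, nonlinear
trajectories, arm–leg correlation beyond shared covariates, and visit-time
jitter (everyone is measured at the nominal months). Passing tests
therefore certify the estimator and pipeline under the model's own
assumptions, not robustness to real-data violations of them.

## Ingestion conventions

The left side is carried unless its exclusion flag is set (then the
contralateral side, recorded in the log); a flagged-or-missing pair marks
the record incomplete. LMI = LM/height² (height stored in cm, converted to
m), LM/BMI = LM/BMI. Appendicular LM doubles the carried side:
ALM = 2·(leg + arm); appendicular BMD is the mean of the two regional
densities (an approximation — areal weights are not available at this
granularity). Glucocorticoid users are excluded before anything else;
complete-case filtering requires every analysis variable at all three
visits and logs counts at each stage. No imputation anywhere.

## Problem sizes used by the checks

The statistical suites run at sizes chosen to give tight Monte-Carlo
error while staying desk-sized: χ² calibration uses 500 replicates of
n = 1000 cohorts (mean χ² vs df, 5% rejection, RMSEA-interval coverage);
parameter recovery uses 100 seeds at n = 10⁴ (95% CI coverage pooled over
the nine structural coefficients); the repeated-measures type-I check uses
120 replicates at n = 120; the bootstrap cross-check of the delta-method
indirect SE uses 500 resamples at n = 800; generator/algebra consistency
is checked at n = 10⁵. Each is a package choice recorded here so the
suites are reproducible as stated.

## Known limitations

- Observed-variable analysis only: no latent variables, no FIML for
  missing data, no robust/sandwich corrections, no categorical estimation.
- The contemporaneous direction (muscle→bone within visit) is assumed, not
  identified.
- The df = 5 vs df = 6 parameterization ambiguity is exposed as a switch;
  published tables that print df = 5 presumably freed one disturbance
  covariance, but the exact choice is not recoverable.
- Standardized-coefficient SEs use the delta method; re-fitting on
  correlation matrices would give slightly different SEs.
- Appendicular BMD as the mean of leg and arm BMD under-weights the legs
  relative to a true area-weighted density.
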