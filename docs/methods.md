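# Methods

## Observation model

The unit of analysis is an arm-visit: at week `t` in arm `j` of trial `i`,
`n` of `N` patients meet a binary endpoint (clinical remission, clinical
response, or endoscopic improvement; each endpoint gets its own model).
The default likelihood is exact binomial,

    N_response,ijt ~ Binomial(N_ij, P_ijt),
    P_ijt = expit(E0(t) + E_drug(t, dose) + eta_ij),

which is self-weighting (larger arms carry more information) and remains
well defined at proportions of 0 or 1. A weighted-normal alternative treats
the observed proportion as Gaussian with SD `sigma * sqrt(P(1-P)/N)`; in
that formulation `sigma` is a free parameter and an AR1 or
compound-symmetry correlation across the visits of one arm can be switched
on. The two observation models are alternatives selected by configuration,
never mixed in one fit. AR2 and ARMA structures are not implemented
(documented limitation).

Probabilities entering log terms are floored at 1e-8: the remission placebo
intercept (B ~ -39 on the logit scale) drives predicted probabilities into
underflow territory at t = 0.

## Structural components

**Placebo.** Exponential `E0 = B + A(1 - exp(-k_pbo t))` (remission), or a
restricted cubic spline in `t` (response, endoscopic; Harrell basis, linear
tails beyond the boundary knots), or a polynomial of degree <= 3 (candidate
form, never selected). Spline knots default to the 10th/50th/90th
percentiles of observed visit weeks; the packaged models use {2, 8, 24}.

**Drug effect.** `E_drug = onset(t) * f(dose)` with `onset = 1 - exp(-k t)`
when a drug (or drug class — the three JAK inhibitors share one `k` in the
response model) shows a resolvable time lag, else 1. `f(dose)` is one of:
dose-independent Emax (ED50 fixed to 0 — the common case, since most drugs
contribute too few dose levels to resolve ED50), sigmoidal Emax with the
Hill coefficient fixed to 1, or `slope * dose`. Distinct regimens of one
drug can carry an Emax override (upadacitinib 45 mg once daily in the
response model).

**Between-arm heterogeneity.** One `eta_ij ~ N(0, omega^2)` per arm enters
additively on the logit linear predictor rather than on a named structural
parameter: the generic arm-level deviation keeps probabilities in (0,1) for
any eta and makes the arm the exchangeability unit used by the bootstrap.

## Covariate model

Arm-level covariate means adjust either the placebo asymptote or the drug
effect magnitude, additively (`P + (COV - COV_mean) * theta`) or as a power
(`P * (COV/COV_mean)^theta`). Two choices here were genuinely open and are
recorded as package assumptions:

* **Form per effect.** Coefficients of order 1 (disease duration,
  corticosteroid use) are treated as power exponents; small-magnitude
  coefficients (prior anti-TNF %, age, the endoscopic duration effect) as
  additive per-unit effects. Rationale: an O(1) per-year additive effect
  would swing logits by ~5 across the observed duration range, and a power
  form is undefined for prior-TNF values of 0 (which occur: the infliximab
  trials are anti-TNF naive). Both forms are implemented; the packaged
  model files record the chosen mapping, and the configuration can express
  either.
* **Target semantics.** Drug-effect covariates scale/shift the
  dose-response magnitude (Emax, or slope*dose) *before* onset
  multiplication — never the raw slope, whose scale differs by orders of
  magnitude. Placebo covariates act on the asymptotic placebo logit `B + A`
  for the exponential form (adjusting the parameter A alone is
  catastrophically amplified when B and A are individually large and
  opposite-signed, as here), and on the time-varying (non-intercept) part
  of spline forms for power effects or the whole `E0` for additive ones.
  At the reference covariate means every adjustment reduces to the
  unadjusted model to machine precision.

Reference means: disease duration 7.53 years; other covariates use the
pooled-table medians (age 41.2 y, prior anti-TNF 22.4%, corticosteroid
46.0%).

A known tension is kept at face value: the endoscopic prior-TNF effect on
drugs (-2.85e-2 per percentage point, additive under the chosen mapping)
drives predicted drug effects negative in arms with very high prior-TNF
fractions. Week-12 rankings in the simulation population (50% prior TNF)
are unaffected because the shift is common to all drugs.

## Estimation

Maximum likelihood. The one-dimensional eta integral per arm is evaluated
by adaptive Gauss-Hermite quadrature: Newton iteration (vectorized across
arms) finds the conditional mode and curvature, and 9 mode-centered,
curvature-scaled nodes (default; configurable) evaluate the integral. A
Laplace option exists; `omega^2 = 0` reduces exactly to the conditional
likelihood at eta = 0. Quadrature accuracy is cross-checked in the tests
against adaptive numerical integration.

Optimization is bounded L-BFGS-B with seeded jittered restarts (5 by
default) because exponential-onset likelihoods can be multimodal in the
rate constants; k-type rates are bounded in (1e-4, 10) per week, variances
at 0, `|rho| < 0.99`. The Hill gamma is fixed to 1 unless explicitly
freed. Wald 95% intervals come from the inverse numerical Hessian when it
is positive definite; bootstrap percentile intervals override them when
requested. Single replicates can push weakly identified parameters (a drug
onset rate, the individual B and A of the exponential placebo) to a bound
or to wide intervals — what the data pin down is `B + A`; replicate
medians center on the generating values.

Model comparison uses the likelihood-ratio chi-square for nested pairs
(nesting checked by free-parameter-name subset) plus AIC; forward stepwise
covariate selection accepts, per round, the candidate with the smallest
LRT p-value if p < 0.05 and the AIC improves, logging every trial fit and
skipping non-converged candidates.

## Validation

* **Bootstrap:** arms are resampled with replacement, stratified into
  placebo and active strata. The arm is chosen as the resampling unit
  because it is the model's exchangeability unit (one eta per arm);
  trial-level resampling is a documented non-goal. Non-converged
  replicates are dropped and counted, not retried. Fully reproducible by
  seed.
* **VPC:** responder counts are simulated per arm-visit (eta draw plus
  binomial noise), and 2.5/50/97.5 percentile bands are formed at each
  exact design time (no binning — visit times are few and shared).
  Coverage is the fraction of observed proportions inside the central 95%
  band; on self-simulated data it sits slightly above 0.95 because the
  binomial outcome space is discrete.
* **Residuals:** conditional weighted residuals
  `(obs - pred)/sqrt(pred(1-pred)/N)` with predictions at the per-arm
  posterior mode of eta (empirical Bayes); with `omega^2 = 0` they are
  standardized to mean ~0, variance ~1 on data simulated from the model.

## Simulation and ranking

Parameter uncertainty propagates by multivariate-normal draws from the fit
covariance (clipped to the parameter bounds) or by resampling bootstrap
rows; an independent eta per treatment per draw adds between-arm
heterogeneity to the bands (a flag disables it for typical-value
prediction). Placebo is evaluated under the same parameter draw as every
treatment, so placebo-corrected differences are formed within draws before
taking medians. The default grid is weeks 1-60 with the headline
comparison at week 12; the default hypothetical population has 7 years
disease duration, age 40, 50% prior anti-TNF, 50% corticosteroid use.
Ranking is by placebo-corrected median, descending, ties broken by
narrower 95% band then name (flagged).

ET90 — time to 90% of the asymptotic effect — is exposed on two scales
because published onset times mix them: the onset-factor scale `ln(10)/k`
and the response-probability scale (bisection root of
`P(t) = 0.9 P(inf)`, tolerance 1e-6 weeks; defined only where an
asymptote exists, i.e. exponential placebo background).

## Synthetic data generator

The packaged design reproduces the published pool's margins exactly — 35
trials, 95 arms, 15,585 patients, 32 placebo arms, per-drug trial/arm/
patient counts — which requires four two-drug (head-to-head) trials, three
of them without a placebo arm. Arm-level covariates are drawn from normals
truncated to the published per-drug median (range), with spread range/4
(only medians and ranges are published). Weight is unreported for three
drugs and is emitted missing, exercising mean imputation; within-trial
covariate correlation is unreported and covariates are drawn
independently. Visit schedules are not published per trial; all arms get
induction visits {2, 4, 6, 8, 12} and maintenance-flagged trials add
{24, 44, 52, 60}. Doses recorded per kg (infliximab, ustekinumab) are
normalized to mg at a 70 kg reference weight. The between-arm variance
(omega^2 = 0.05, SD ~0.22 logit) and residual scale (sigma = 1) are not
published; they were set once to values typical of arm-level
heterogeneity in this literature.

Placebo spline coefficients for the response and endoscopic models are not
published either; the packaged values were fixed once by least squares
against a target time-course (response placebo rising to ~30% with a mild
post-peak decline — which also imparts the secondary-loss-of-response
shape to time-constant drugs — endoscopic plateau ~21%) and give week-12
typical values close to the published simulation read-outs under the
published drug parameters. Etrasimod has no published remission effect, so
remission datasets drop its trials entirely (32 of 35 trials report
remission in the synthetic pool).

What passing tests show — and what they do not: the generator matches the
model family used for fitting, so parameter-recovery and calibration
results demonstrate the correctness of the machinery under the stated
design, not robustness to model misspecification, reporting bias,
digitization error, or correlated covariates in the real literature.

## Problem sizes and numerical defaults

Replicate recovery studies use the half-scale design (~7,800 patients,
~500 arm-visits per endpoint) with 20 replicates and single-start
optimization initialized at the generating values — the standard protocol
for simulation-based estimator checks. Convergence tolerance 1e-8
(L-BFGS-B ftol), iteration cap 2000, quadrature 9 points (7 vs 15 agree to
<1e-4 on these data). Bootstrap and VPC defaults mirror the study
procedure (1,000 replicates / 1,000 simulations; simulation 10,000 draws);
tests and examples use smaller counts for speed.
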