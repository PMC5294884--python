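# Methods

This note records the statistical model behind `patmix`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real registries.

## Model and procedure

The analysis variable is a 4-level categorical (Dukes' stage A–D) that is
partially missing; the outcome is binary 30-day postoperative mortality
(MORT); age is dichotomised at 70 years (AGE). The four missingness
pattern cells are r = 1 (AGE=0, MORT=0), 2 (AGE=0, MORT=1), 3 (AGE=1,
MORT=0), 4 (AGE=1, MORT=1).

**MAR imputation.** Chained equations with a reference-category
multinomial logit for stage (reference stage A) and binary logits for any
other incomplete binaries. Each cycle refits the imputer on the rows where
the target was observed, draws coefficients from N(θ̂, V̂(θ̂)), and redraws
the missing values from the implied predictive distribution. This is
approximate proper imputation: the parameter draw propagates estimation
uncertainty into between-imputation variance, without a full Bayesian
posterior. Defaults m = 10 imputations, 10 cycles. Missing entries are
initialised from observed marginals; variables are visited in decreasing
order of missingness.

**MAR profile.** Per imputed dataset the multinomial logit of stage on
(MORT, AGE) is fitted and converted by the softmax to per-patient
probabilities; these are averaged within cells (they are constant within a
cell, since the two covariates determine it) and pooled across imputations
by Rubin's rules on the scale log(p_rj / p_rA), back-transformed with a
delta-method standard error. Raw-scale pooling is available and agrees to
well under 0.005 at the sample sizes involved. The main-effects model is
not saturated on the four cells (9 parameters vs 12 free probabilities);
adding the AGE×MORT interaction makes it saturated, and the test suite
uses that as an internal oracle against plain cell frequencies.

**Elicitation and the Dirichlet prior.** Expert v's response for cell r is
a probability vector over stages; the aggregate is the mean π̂_rj and the
sample variance V̂_rj (divisor K−1, so K ≥ 2). Mean rows are renormalised
to the simplex (questionnaire rounding leaves raw sums at 0.99–1.01);
variances are left untouched. The Dirichlet marginal variance
π(1−π)/(S+1) gives a per-category concentration-sum estimate
S_rj = π̂(1−π̂)/V̂ − 1, pooled into E[S_r] by the arithmetic mean
(median and precision-weighted pooling are available behind a switch and
recorded in the spec JSON); finally γ_rj = E[S_r]·π̂_rj, so the prior mean
equals the elicited mean by construction. Degenerate inputs are rejected
rather than patched: V̂ = 0 (all experts identical) needs an explicit
variance floor, V̂ ≥ π̂(1−π̂) implies a non-positive concentration, and an
elicited mean of exactly 0 or 1 leaves the Dirichlet family.

**MNAR re-imputation.** One Dirichlet draw per (imputation × cell), then
independent categorical redraws of every originally-missing stage in that
cell, observed values untouched. The per-cell granularity is what lets
prior spread reach Rubin's between-imputation variance: the between-
imputation variance of a re-imputed cell frequency follows the
beta-binomial form π(1−π)[1/n + (1−1/n)/(S+1)], against which the tests
check. A per-record variant is exposed for comparison; it averages the
prior away within each imputation and understates prior uncertainty.

**Pooling and comparison.** The substantive model is a single-level
logistic regression of mortality on stage and configured covariates with
fixed reference levels (stage A, female, elective, quintile 1, colon,
Charlson 0). Rubin's rules: Q̄ = mean, W = mean squared SE, B = sample
variance, T = W + (1+1/m)B, large-sample MI degrees of freedom
ν = (m−1)(1 + W/((1+1/m)B))²; the Barnard–Rubin small-sample adjustment is
available by flag. The sensitivity report gives, per coefficient, the two
pooled odds ratios, 100·(OR_MNAR − OR_MAR)/OR_MAR (MAR is always the
denominator, for increases and decreases alike), flags for a point
estimate falling outside the other assumption's CI, and a
direction-of-association agreement indicator. A multilevel (cluster)
substantive model is deliberately out of scope: the imputation makes no
cluster adjustment either, and the MAR-vs-MNAR contrast — the point of the
tool — is unaffected; the synthetic registries carry no cluster structure.

## Synthetic registry

The generator emulates a national colorectal-resection registry:
~53% of patients over 70, 30-day mortality 6.8%, three-quarters elective
admissions, uniform deprivation quintiles, Charlson bands
(0.70, 0.18, 0.08, 0.04), tumour sites (colon 0.60, rectosigmoid 0.10,
rectum 0.30), diagnosis years 1998–2006, age uniform on [40, 90] (only the
dichotomised AGE is used downstream, so the age marginal is a
convenience). Stage comes from the same two-covariate multinomial logit
the analysis profiles — the congenial case, which makes parameter recovery
and interval coverage well-posed checks. The default stage parameters give
cell-wise distributions of the shape seen in such registries (stage C most
common; stage D enriched among early deaths, 0.20 vs 0.12 at ≤70).

Stage is blanked per cell with default rates (0.16, 0.25, 0.14, 0.22) for
r = 1..4 — missingness roughly 60% more frequent among the deceased — under
one of three mechanisms: MCAR (single rate, the mean of the four),
MAR-on-cells (the cell's rate), or MNAR-on-stage (cell rate's log-odds
shifted per true stage). The truth mask of blanked entries is returned for
recovery testing only; no analysis module consumes it.

When an outcome model is configured, the generative order is stage | AGE
followed by MORT | stage, AGE (a coherent DAG with mortality downstream of
stage); the stage model's MORT coefficients are then unused, since stage
cannot be drawn given an outcome that is itself drawn given stage. Without
an outcome model, MORT comes from its marginal and stage from the full
(MORT, AGE) logit.

What the generator does *not* emulate: the joint covariate dependence of a
real registry (covariates other than stage/AGE/MORT are independent
draws), hospital-trust clustering, secular trends, and missingness in more
than one variable by default. Passing tests therefore demonstrate the
*machinery* — calibration under congeniality, correct prior propagation,
correct arithmetic — not robustness to real-data complications such as
uncongenial imputation models or informative cluster effects.

## Direction of the sensitivity effect

Which way the stage odds ratios move under MNAR depends on the *shape* of
the elicited prior across cells, not merely on whether stage D is
inflated:

* A prior **flat across cells** ("the missing are late-stage whether or
  not they survived", the bundled `LATE_STAGE_SHIFT_*` prior) carries less
  stage–mortality contrast than the MAR profile. Replacing MAR
  imputations with its draws dilutes the association among the ~15% of
  imputed patients, attenuating the stage ORs — the classic reassuring
  pattern, reproduced by the direction test (median stage-D change over
  replicates ≈ −10%).
* A prior **anchored cell by cell near the MAR profile but with a
  sharper mortality gradient** (the bundled `DEMO_ELICITED_*` prior:
  stage D doubled among the deceased cells, stage A raised among
  survivors and lowered among the deceased) *strengthens* the
  stage–mortality contrast among the imputed values, and the stage ORs
  increase. This follows from counting: with that prior, the implied
  cross-cell odds ratio for D vs A among the missing is ≈ 8.8 against
  ≈ 2.7 under the MAR profile.

Both behaviours are correct outputs of the same mechanism; the package
ships both priors, reports both in the acceptance script, and treats the
attenuation case as the direction property because only its premise — a
prior that weakens the imputed stage–outcome association — logically
forces the sign. In a real elicitation exercise, which regime applies is
an empirical property of the experts' answers relative to the imputation
model's missing-subgroup distribution, not something the analyst chooses.

## Numerical choices

* Multinomial/logistic fits use an in-package damped-Newton solver that
  aggregates duplicate design rows (binary covariates make fits
  effectively O(cells), so a chained-equations run costs seconds at
  n = 10⁵). The unpenalised fit matches statsmodels `MNLogit` to ~1e-13
  (params) / 1e-8 (SEs), which the tests assert. A weak ridge penalty
  (default 1e-4 in the imputer, 0 in the profiler) stabilises separated or
  sparse fits; singular or non-converging fits raise a separation error
  naming the remedy rather than returning garbage.
* Coefficient draws use an explicit Cholesky factor (jittered by ~1e-10 on
  failure) so runs are bit-reproducible for a given seed; every random
  stage derives its generator from a (seed, stream) `SeedSequence`, and
  per-imputation generators are spawned children, so imputations are
  independent but deterministic.
* Softmax computations subtract the row maximum before exponentiating;
  categorical draws clamp the final cumulative weight to 1 to absorb
  rounding shortfall.
* Elimination p-values use likelihood-ratio tests (invariant to
  parameterization, unlike Wald) with all levels of a categorical dropped
  jointly; "most predictive" ranking, needed to reduce elicitation to two
  covariates, is by joint p-value with |log OR| as tie-break.
* Report tables round probabilities to 2 decimals (the precision at which
  elicitation panels are shown); full precision is kept internally.

## Problem sizes used in tests and acceptance

Simulation checks run at n = 20,000 for single-run recovery, n = 100,000
for missingness-rate and mechanism checks, and n = 5,000 × 200 replicates
(m = 10, 10 cycles) for interval coverage; the direction property uses 50
replicates at n = 5,000. These sizes put Monte-Carlo error comfortably
below the effects being measured while keeping a full run to a few
minutes on one CPU.

## Known limitations

* Only logistic/multinomial imputer families; no predictive mean
  matching, no continuous-variable imputation, no multilevel imputation.
* The elicitation aggregation treats experts as exchangeable; no
  behavioural weighting, and the pooling of per-category concentration
  estimates (mean/median/precision) is a modelling choice the spec JSON
  records rather than a derived quantity.
* MNAR standard errors are not guaranteed to exceed MAR ones; they
  reflect the elicited spread, which can be narrower than the MAR
  predictive spread.
* The backwards-elimination step is complete-case and inherits the usual
  caveats of stepwise selection; it is used here only to choose an
  elicitation frame, not for inference.
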