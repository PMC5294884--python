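# patmix

Pattern-mixture sensitivity analysis for multiply-imputed categorical data.

## The problem

Registry analyses routinely handle missing data by multiple imputation (MI)
under the *missing at random* (MAR) assumption: missingness is independent
of the unobserved values given what was observed. MAR is untestable, so a
careful analysis asks how much the substantive conclusions would move if
the missing values were in fact systematically different from the observed
ones (*missing not at random*, MNAR).

`patmix` implements a practical pattern-mixture answer for a 4-level
categorical variable — the motivating setting is Dukes' stage (A–D) in a
colorectal-cancer surgery registry with a binary 30-day postoperative
mortality outcome:

1. **Find missingness predictors.** Regress a binary indicator of the
   stage being missing on candidate covariates; backwards-eliminate at the
   1% level with joint likelihood-ratio tests for multi-level covariates.
   The two strongest predictors — dichotomised age (≤70 / >70) and 30-day
   mortality — define four *pattern cells* r = 1..4.
2. **Impute under MAR.** Fully conditional specification (chained
   equations) with a multinomial-logit imputer for stage; m = 10 imputed
   datasets, 10 cycles, with coefficient draws from the asymptotic normal
   at every cycle (approximately proper imputation).
3. **Profile the MAR assumption.** Per imputed dataset, fit

   ```
   log P(stage = j) / P(stage = A) = α_j + β_j1 MORT + β_j2 AGE ,   j = B, C, D
   ```

   convert to per-patient probabilities P̂_ij by the softmax, average
   within cells to get P̂_rj = E[P̂_ij | r], and pool across imputations
   with Rubin's rules.
4. **Elicit expert beliefs.** Show the table P̂_rj to experts and ask what
   they believe the probabilities are *in the missing data*. Aggregate K
   experts' answers into means π̂_rj and between-expert variances V̂_rj,
   then moment-match a Dirichlet prior per cell:

   ```
   S_rj  = π̂_rj (1 − π̂_rj) / V̂_rj − 1        (from Var = π(1−π)/(S+1))
   E[S_r] = mean_j S_rj
   γ_rj  = E[S_r] · π̂_rj
   ```
5. **Re-impute under MNAR and compare.** For each imputation and each
   cell, draw p ~ Dirichlet(γ_r) and replace every originally-missing
   stage in that cell with a Categorical(p) draw. Fit the substantive
   logistic model of mortality on stage and covariates to both stacks,
   pool with Rubin's rules (Q̄, W, B, T = W + (1+1/m)B), and report
   odds-ratio changes and outside-CI flags per coefficient.

Because the real registry is not publicly deposited, the package ships a
synthetic-registry generator with the same analytic structure (stage drawn
from the two-covariate multinomial logit; per-cell missingness rates
defaulting to 0.16 / 0.25 / 0.14 / 0.22; optional stage-dependent mortality
and stage-dependent missingness), which makes every stage of the pipeline
testable end to end.

## Worked example

```python
import patmix as pm

cfg = pm.PipelineConfig(
    out_dir="runs/demo", seed=11, m=10, cycles=10,
    synthetic_prior="late-stage",
    generator=pm.GeneratorConfig(n_patients=20_000, outcome_model=pm.OutcomeModel()),
)
pm.run_pipeline(cfg)
```

or, equivalently, from the shell: `patmix run --seed 11 --out runs/demo`
(plus per-stage subcommands `simulate`, `impute`, `profile`, `template`,
`fit-prior`, `reimpute`, `analyse`, `compare`).

The run directory contains the MAR stack, the pooled cell-probability
table (the panel experts are shown):

```
                                     cell     A     B     C     D
1  alive 30 days after surgery, age <= 70  0.14  0.35  0.40  0.11
2   dead 30 days after surgery, age <= 70  0.09  0.29  0.42  0.21
3   alive 30 days after surgery, age > 70  0.13  0.44  0.36  0.07
4    dead 30 days after surgery, age > 70  0.09  0.38  0.40  0.14
```

and the sensitivity report. With the bundled "late-stage" prior (experts
believe patients with missing stage are late-stage whether or not they
survived: π = (0.08, 0.27, 0.35, 0.30) in every cell), the stage odds
ratios attenuate under MNAR while age is untouched:

```
coefficient                              AOR (MAR)       p            AOR (MNAR)       p   change
stage_B                           1.25 (0.95-1.63)   0.107      1.17 (0.87-1.57)   0.292    -6.2%
stage_C                           1.60 (1.22-2.11)  <0.001      1.41 (1.06-1.88)   0.020   -12.2%
stage_D                           2.75 (2.03-3.72)  <0.001      2.23 (1.57-3.18)  <0.001   -18.7%
AGE                               2.37 (2.07-2.71)  <0.001      2.34 (2.04-2.69)  <0.001    -1.0%
```

Reading: if the experts are right that the missing patients are
disproportionately late-stage regardless of survival, the MAR analysis
overstates the stage–mortality association by roughly a fifth for stage D
— the direction of risk and the qualitative conclusions survive, which is
what a reassuring sensitivity analysis looks like. A prior anchored cell
by cell near the MAR profile but sharper in its mortality contrast moves
the stage ORs the other way; `docs/methods.md` works through why.

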