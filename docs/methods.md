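# Methods

This note documents the statistical model behind `polymix`, the choices
made where the design was genuinely open, and what the synthetic cohorts
do and do not demonstrate.

## Disease model

The simulator and all downstream reasoning use a logistic ("logit-
liability") disease model. For person *i* in ancestry *a*:

    logit P(case_i) = α_a + Σ_t λ_{a,t} · s_{i,t} + β_age · z(age_i) + β_sex · sex_i

where `s_{i,t}` are trait-level polygenic scores drawn multivariate normal
with unit variances and a configurable correlation matrix, `λ_{a,t}` are
per-ancestry liability loadings (attenuated loadings model reduced
cross-ancestry transferability), age is uniform on `age_range` and enters
standardized, and sex is Bernoulli(0.5). The intercept `α_a` is solved by
bisection on the Monte-Carlo expectation of the prevalence over the
simulated covariates, to a tolerance of 1e-3, so the expected prevalence
equals the configured `K_a`. A probit liability variant is deliberately
out of scope: every evaluation step downstream is logistic regression, so
a logistic liability keeps generator and analysis on one scale.

Age is standardized with the closed-form moments of its uniform
distribution (mean `(lo+hi)/2`, SD `(hi−lo)/√12`) rather than sample
moments, so each ancestry's intercept solve is independent of the other
ancestries' draws and the generator is exactly reproducible per stratum.

Principal components: the first two PCs carry ancestry-specific offsets
placed on a circle of radius `pc_separation`; the remaining PCs are pure
standard-normal noise. This is the minimal structure needed to exercise
PC residualization — it is not a model of real population structure.

### Genotype layer

When `n_variants > 0`, `emit_genotype_layer` draws per-variant allele
frequencies uniform on [0.05, 0.95], dosages binomial(2, f), and per-trait
weights iid N(0, 1/m) (so trait scores have O(1) variance). Each trait's
score column is **replaced** by the exact dot product of the complete
dosage matrix with the weights; the scoring engine's output can therefore
be compared with simulated truth exactly. Because the replacement severs
the original scores' link to the already-drawn outcome, case status is
then redrawn from the same liability model using the replaced scores,
standardized by their exact binomial moments (mean `Σ 2 f w`, variance
`Σ 2 f (1−f) w²`), with intercepts re-solved. Missingness is masked in
*after* the truth scores are stored, so the mean-imputation path is
testable against a brute-force oracle.

## Scoring semantics

`compute_scores` mirrors PLINK2 `--score`: the counted allele of each
dosage column is matched to the effect allele (direct), the other allele
(flipped, dosage becomes `2 − d`), or their strand complements —
except for strand-ambiguous A/T and C/G pairs, which cannot be resolved
and are dropped when `drop_ambiguous` is set. Missing dosages are imputed
with the variant's mean observed dosage. Sum mode is the default: the
downstream residualization and standardization make the absolute scale
irrelevant, and sums avoid per-person denominators under missingness.
Average mode divides by `2 × (number of used variants)`. Variants in the
weight file that are absent from the dosage matrix are excluded and
counted in the alignment report; there is no proxy/LD lookup.

## Adjustment

Raw scores are regressed on an intercept plus the first `n_pcs` PCs
(default 20) by OLS, and the residuals standardized with the **sample**
SD (n−1), matching the default of mainstream statistics software.
The fit happens within the evaluation set itself (the field's usual
practice for PGS evaluation); a `project` function supports fitting in a
tuning set and projecting to held-out persons for leakage-averse users,
default off. The order contract is: residualize pooled → standardize
pooled → subset by ancestry. Ancestry subsets therefore need not have
mean 0 — that is intended, and asserted in tests. All-zero PC columns are
dropped from the design with zero coefficients (the intercept-only
degenerate case); genuinely collinear PCs raise an error naming the
offending columns.

## Mixing weights

Component scores are combined by one joint maximum-likelihood logistic
regression of case status on all components, with no covariates and no
penalty. Collinearity is surfaced as an error, never silently
regularized; perfect separation or non-convergence within 100 iterations
is refused. Negative fitted coefficients remain active in the linear
combination (the signed coefficients are always reported) but are floored
at zero for the contribution percentages — signed shares cannot be
normalized to 100% meaningfully. Contributions are computed from per-SD
coefficients (coefficient × component sample SD): for standardized inputs
this is a no-op, and it makes the reported percentages invariant to
rescaling any component, which raw-coefficient shares are not. The
combined score's intercept is irrelevant because the combination is
re-standardized before evaluation.

The two-score case (an ancestry-specific score plus an all-ancestry
score) is the same operation restricted to two components. Tuning-set
filters select ancestry-specific tuning, pooled tuning, or
"everyone-except-X" tuning (used when ancestry X's own tuning subset is
too small); there is no separate code path.

## Metrics

* **OR per SD** — logistic regression of case on score + age + sex
  (optionally + PCs, used by the tail analyses); Wald 95% CI
  `exp(β ± 1.96·SE)`. Wald rather than profile-likelihood intervals: they
  match the scale of routinely reported PGS CIs.
* **AUROC** — computed from midranks (Mann–Whitney), ties counting ½,
  rather than from univariate-logistic predicted probabilities; a
  univariate logistic model is monotone in the score, so the two are
  identical. CI by Hanley–McNeil.
* **AUPRC** — average precision (step-wise), not trapezoidal
  interpolation, which is known to inflate AUPRC. In the null limit it
  equals the case fraction.
* **Nagelkerke R²** — `[1 − exp((2/n)(LL₀ − LL_m))]/[1 − exp((2/n)LL₀)]`,
  reported incrementally over an age+sex base model as
  `(R²_full − R²_base)/(1 − R²_base)`.
* **Liability-scale R²** — the Lee et al. (2012) transformation of the
  observed-scale case-control R²: with threshold `t = Φ⁻¹(1−K)`, density
  `z = φ(t)`, case mean liability `m = z/K`,

      C = K²(1−K)² / (z² P(1−P)),   θ = m(P−K)/(1−K) · (m(P−K)/(1−K) − t)
      R²_liab = C·R²_obs / (1 + C·θ·R²_obs)

  where `K` is the population prevalence and `P` the sample case
  fraction (θ = 0 when P = K). The transformation is fed the
  observed-scale incremental R² from linear-probability fits — the scale
  on which the formula is derived — not the Nagelkerke value, which is
  reported separately. The probit-based constant is used even though the
  combined pipeline is otherwise logistic; on real data the two
  conventions are sometimes conflated under "logit-liability" wording,
  and this is the variant with a recovery guarantee (validated in the
  acceptance suite: a liability-threshold simulation with true liability
  R² = 0.10 is recovered within ±0.02 at n = 100,000).

## Stratification

Percentiles are `ceil(100·rank/n)` with average ranks for ties; per-bin
prevalence gets Wilson 95% CIs. The extreme-tail search scans a fixed
grid of tail sizes from 50% of the population inward (default step 0.1
percentage points; the study pipeline uses 0.5 as its desk-scale default)
and, at each candidate cut, fits a logistic regression of case status on
tail membership plus covariates, restricted to the tail plus the middle
quintile (percentile bins 41–60; persons in both — only possible for cuts
above 40% — count as tail). It returns the **largest** tail whose OR
point estimate meets the fold criterion, consistent with monotone
reported proportions across 3-/4-/5-fold thresholds; a CI-bound criterion
is available as an option. Each fold is fitted independently on the
shared grid (no nesting is enforced; nesting of the point-estimate
criterion is verified empirically on simulated cohorts). The middle
quintile is identical across folds and sides for a given score.

## Pipeline

`run_study` derives per-stage seeds from one master seed via named
`SeedSequence` substreams, splits 30/70 by plain unstratified
randomization, adjusts scores within each set, fits pooled and
per-ancestry mixing models (skipping ancestries with fewer than 20 cases
or controls in tuning, with a log message), evaluates every single-trait
score plus both combined variants per ancestry — using each ancestry's
empirical validation prevalence as K — and stratifies one designated
ancestry. A manifest records seeds, counts and SHA-256 hashes of every
artifact; `check_manifest` re-verifies hashes and the
tuning/validation disjointness guard.

## What the simulations do and do not show

The generator reproduces the *statistical shape* the method assumes:
correlated multivariate-normal trait scores, a logistic liability,
ancestry-separating PCs, ancestry-specific prevalence and attenuated
loadings. It omits LD structure, admixture tracts, relatedness,
genotyping error, imputation quality, phenotyping noise, and realistic PC
geometry. Passing tests therefore demonstrate that the *procedures* are
correct (scoring arithmetic, adjustment contracts, weight recovery,
metric calibration, tail-search oracle equivalence) — not that any
particular real-data performance level will be attained. Absolute metric
values from the default synthetic study depend on the chosen loadings and
correlations, which are plausible-by-construction defaults, not estimates
of any real cohort.

## Problem sizes and tolerances

Default study sizes (acceptance script): 50,000 persons across four
ancestry groups (24k/10k/10k/6k), eight component traits, 20 PCs, 30/70
split, tail grid step 0.5. Test-suite recovery checks use n = 20,000
(mixing weights, OR/SD), n = 50,000 (null behavior, calibration) and
n = 100,000 (liability R²), with a coarser tail grid (step 1.0) for the
repeated-scan checks. Exact contracts are asserted at 1e-10 (adjustment
moments, orthogonality, Lee-transformation dual implementation,
imputation oracle) or exactly (AUROC vs pair counting, engine vs
simulated truth, tail cut vs exhaustive scan). Bisection tolerance for
prevalence calibration is 1e-3 on the expected prevalence; logistic fits
are refused after 100 iterations without convergence.

## Known limitations

* No PLINK binary formats (.bed/.pgen); text `.raw` and VCF only.
* No LD-aware weight estimation — per-variant weight files are inputs.
* Multi-allelic VCF sites keep the first ALT allele only (flagged).
* The tail search refits the full grid per fold; for very large cohorts
  with a 0.1-point grid this is the dominant cost.
* Mixing-weight contributions for components with negative coefficients
  are reported as 0%; interpret the signed coefficients alongside.
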