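# Methods

## The model

`polymediate` estimates how much of the association between a polygenic
risk score and a continuous outcome travels through a measured behavioural
mediator. The system is a recursive pair of linear structural equations:

    M = i_a + a·X + γ_aᵀC_a + ε_m          (mediator equation)
    Y = i_b + c′·X + b·M + γ_bᵀC_b + ε_y   (outcome equation)

with X the internally z-standardized genetic risk score
(X = Σ_j w_j d_ij, standardized within cohort), M an eating-behaviour
score, Y BMI, and C_a / C_b the covariate sets of the two equations (they
may differ: the fully adjusted model controls the mediator equation
additionally for smoking). The estimands are the product-of-coefficients
quantities

    indirect = a·b,  total = c′ + a·b,
    proportion mediated = 100·(a·b)/(c′ + a·b).

Because the system is recursive with unrestricted, possibly correlated
Gaussian errors, equation-by-equation least squares is the maximum-
likelihood "simultaneous" fit; `fit_paths_joint` verifies the identity by
solving the stacked block system in one pass.

The proportion mediated is suppressed (reported as a marker, not a number)
when the indirect and total effects have opposite signs — inconsistent
mediation, where a percentage would be misleading — or when the total
effect is zero.

### Standardization

Continuous exposure, mediator and outcome are z-scored on the
complete-case analysis sample before fitting, so all reported
coefficients are standardized betas; binary covariates enter as 0/1
indicators. The convention is the usual one for comparing path
coefficients across cohorts with different raw scales. Passing
`standardize=()` in a `MediationSpec` keeps every variable on its raw
scale (used, for instance, by the measurement-error oracle below).

### Inference

Uncertainty comes from a case-resampling bootstrap: individuals are drawn
with replacement, all equations are refit per replicate (default 1000
replicates), and 95% intervals are the 2.5/97.5 empirical percentiles of
the replicate draws. Percentile intervals are the default because the
product a·b has a skewed, non-normal sampling distribution at these
effect sizes. Standard errors are the standard deviation (ddof=1) of the
replicates. Replicates with a singular resampled design are redrawn, with
a hard cap of 10× the replicate count. The replicate solves are vectorised
normal-equation solves in chunks of 200, which keeps a 1000-replicate fit
on a cohort of ~2000 under a second on one CPU.

When the two covariate sets differ, total = c′ + a·b is no longer an
algebraic identity with the refit reduced-form coefficient; the package
composes the total (matching the published definition "sum of the direct
and indirect effects"), also reports the refit value, and logs a warning
when the two differ by more than 0.01.

### Model checks

Linearity of the exposure→mediator relation is checked with a Gaussian
likelihood-ratio test against the model augmented with a squared-exposure
term (statistic n·log(RSS₀/RSS₁), χ²₁ reference). The squared-term
alternative is this package's concrete choice of alternative model; the
test is calibrated (type-I error 3–7% at α=0.05 in the acceptance suite).
Residual diagnostics export per-equation residuals with Blom plotting
positions for Q-Q inspection.

## Moderation

Three views of a continuous moderator W (flexible/rigid restraint
scores):

* **Direct-path moderation** — `Y ~ X + W_c + X·W_c + covariates`, where
  W_c is the mean-centred moderator. Centring decorrelates the main and
  product terms (numerical conditioning only; estimates are invariant).
  Simple slopes of X are reported at the moderator mean ∓/+ 1 SD and at
  the stratification threshold.
* **Moderated-mediation** — the outcome equation gains M·W_c, so
  b(W) = b₀ + b_int·(W − W̄) and the conditional indirect effect is
  a·b(W); both are reported, with bootstrap CIs, at the threshold and
  mean ± 1 SD. Interaction p-values are Wald z tests on the bootstrap SE.
* **Stratified mediation** — the conventional dichotomisation: W ≤ 3 is
  "low", W > 3 is "high"; the full bootstrap mediation is refit inside
  each stratum (with its own within-stratum standardization). The percent
  change in mediation is 100·(indirect_high − indirect_low)/total_pooled.
  Published stratified tables are ambiguous about whether the direct
  effect was pooled or stratified (they print identical direct effects in
  both strata); the package emits the fully stratified estimates and the
  pooled direct effect side by side.

A restraint score is never allowed to be simultaneously the mediator and
the moderator of one model; the spec validator rejects it.

## Meta-analysis across cohorts

Path estimates from independent cohorts sharing a mediator construct are
pooled by fixed-effect inverse-variance weighting on their bootstrap SEs
(weights ∝ 1/SE²). With two cohorts a between-cohort variance component
is unidentifiable, making the fixed-effect model the appropriate
precision-pooling choice; Cochran's Q and I² are reported descriptively.
Indirect effects are pooled directly on their own SEs rather than
recomposed from pooled a and pooled b — the two routes do not commute,
and the package deliberately promises only the direct-pooling route. The
combined proportion mediated is recomputed from the combined indirect and
combined total.

## Sensitivity analyses

**Fixed-reliability measurement error.** Under the classical model the
observed mediator is M* = M + u with u independent Gaussian noise, and a
stated reliability ρ = Var(M)/Var(M*) fixes Var(u) = (1−ρ)·Var(M*),
anchored to the observed variance on the analysis sample. The outcome
equation is corrected by the method of moments: Var(u) is subtracted from
the mediator's diagonal entry of the regressor covariance matrix before
solving the normal equations. This is deterministic, and in the
linear-Gaussian case equals the single-indicator latent-variable SEM
solution. If the adjusted covariance loses positive definiteness the
requested ρ is infeasible for the data and the error names the minimum
feasible value (1 − 1/[(S⁻¹)_mm·Var(M*)]).

Path a is left unchanged by the correction: classical error in a
*dependent* variable inflates residual variance without biasing the
slope. That statement is exact on the raw mediator scale; if the observed
mediator is z-scored first, its scale absorbs a factor √ρ and the
"unchanged" convention keeps a on the observed-score SD scale. The
attenuation oracle in the tests therefore runs unstandardized: with
Var(M)=1 in the generator, the naive slope is ρ·b and the corrected one
recovers b. Correcting the outcome equation (rather than path a, or both)
is this package's documented reading of a "reliability fixed to 0.8"
sensitivity analysis.

**Intermediate confounding.** For a variable I (e.g. a depression score)
that may sit between the exposure and the mediator while also affecting
the outcome, a recursive three-equation system

    I ~ X;   M ~ X + I;   Y ~ X + I + M   (all + covariates)

decomposes the total effect into direct, via-M (a_cond·b), via-I (p₁·q)
and serial via-both (p₁·p₂·b) components, each with bootstrap CIs. With
common covariate sets the components sum exactly to the reduced-form
exposure coefficient. Depression and anxiety are handled one at a time,
matching the per-variable sensitivity framing.

## The synthetic-cohort generator

The generator produces exactly the structure the estimators assume, with
known ground truth:

* **Genotypes** — `n_variants` independent biallelic loci in
  Hardy–Weinberg proportions, dosage ~ Binomial(2, MAF), MAFs uniform on
  `maf_range` (default 0.05–0.5). No linkage disequilibrium: the risk
  score is an additive sum, so LD would not change any estimand studied
  here. Per-variant weights ~ Normal(0.02, 0.01) with non-palindromic
  allele pairs.
* **Structural equations on a standardized scale** — the exposure is the
  z-scored risk score; the mediator and outcome equations use the path
  coefficients of the config, with residual SDs solved (by default) so
  both variables have unit population variance. Generating coefficients
  are therefore directly comparable to the standardized betas the
  estimators report. Default truth a=0.10, b=0.43, c′=0.16 — the scale of
  the published disinhibition estimates. An optional affine rescaling
  maps the outcome to BMI-like units (mean 25.4, SD 4.5) for realism; it
  changes no standardized estimate.
* **Moderator** — Normal(3, 1), so the threshold-3 split yields roughly
  balanced strata; it enters the outcome equation centred at the
  threshold, with main effect −0.04 by default and interaction terms
  (mediator×moderator `w_interaction`, exposure×moderator
  `xw_interaction`) defaulting to zero.
* **Covariates** — default one binary (sex-like, Bernoulli(0.6)) and one
  continuous (age-like, standard normal), each with weak effects (0.05 on
  the mediator, 0.10 on the outcome); fully configurable, and the
  pipeline's fully adjusted model adds smoking/ethnicity/depression/
  anxiety-like columns. Covariates enter the structural equations centred
  so generated variables stay zero-mean. No published magnitudes exist
  for these nuisance effects; the defaults are chosen once as plausible
  weak confounding and are not tuned.
* **Measurement error** — classical: observed mediator = true + Gaussian
  noise sized from the empirical true-score variance so that
  Var(true)/Var(observed) equals the configured reliability. The hidden
  true-score column is kept in the phenotype table, enabling
  latent-truth oracles in tests.
* **Intermediate** — optionally I = t_x·X + noise feeding both the
  mediator and the outcome, for sequential-mediation studies.

`implied_moments` returns the closed-form variances the config implies;
the test suite checks empirical moments against them at n = 2·10⁴.
Identical seeds give bit-identical cohorts (seed streams are spawned per
component, so genotypes are reproducible independently of phenotypes).

What the generator does *not* emulate — LD and population structure,
imputation uncertainty, questionnaire item structure and floor/ceiling
effects, non-Gaussian residuals, informative missingness — bounds what
green tests mean: they demonstrate correctness of the estimators under
the assumed linear-Gaussian data-generating process, not robustness of
the scientific conclusions to violations of it.

## Numerical choices and edge cases

* OLS solves use rank-checked `lstsq`/normal equations; rank-deficient
  designs, zero-variance mediators/outcomes or constant moderators are
  hard errors, never silently dropped columns.
* Listwise deletion per model (missing data are not imputed); the dropped
  count is logged, and the two models of one mediator may legitimately
  use different sample sizes.
* Risk-score allele alignment is by exact allele-pair match only: a
  counted allele equal to the table's other allele flips the dosage to
  2 − d; anything else is a hard error (no strand guessing). Palindromic
  A/T and C/G variants are scored as-is with a logged warning.
  Individuals with any missing dosage among scored variants are dropped.
* Display rounding (2 decimals for coefficients, integer percent for the
  proportion mediated) happens only at TSV serialization; JSON output and
  all in-memory results keep full precision.
* Every stochastic stage of the pipeline derives its seed
  deterministically from the single run seed and a stage label, so
  results are reproducible stage by stage and runs are byte-identical
  under a fixed seed.
* No multiple-testing adjustment is applied anywhere, consistent with the
  exploratory framing of per-behaviour models.

## Problem sizes in the test and acceptance runs

Simulation-based checks use cohorts of 1000–8000 individuals with 20–50
variants (bootstrap coverage: 500 cohorts × 1000 replicates at n=1000;
parameter recovery: 200 cohorts at n=2000; attenuation oracle: one cohort
of 100 000), and the acceptance script uses study-sized cohorts (2101 and
1679 individuals, 100 variants, 1000 bootstrap replicates). These sizes
give Monte-Carlo error well inside every stated tolerance while keeping a
full run to a few minutes on one CPU.

## Known limitations

* Single-indicator mediators only; no latent-variable SEM with multiple
  indicators, categorical mediators or survival outcomes.
* The measurement-error correction addresses classical, non-differential
  error only.
* Fixed-effect meta-analysis only (appropriate at k=2, but not a
  random-effects replacement at larger k).
* Moderation of path a and three-way interactions are out of scope.
* The proportion mediated is a ratio estimator; no CI is reported for it.
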