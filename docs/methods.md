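# Methods

## The analysis

`cardiogrs` implements an observational case–control analysis built around an
unweighted additive genetic risk score (GRS) on a small fixed SNP panel.
The stages, in pipeline order:

1. **Cohort assembly.** Samples are included only if they have both genotype
   and questionnaire data; every input sample is either included or excluded
   with exactly one primary reason (`missing_questionnaire`,
   `missing_genotype`, `bmi_outlier`), and conservation
   |included| + |excluded| = |input| holds at every stage.
2. **Phenotyping.** BMI = weight/height² with normal (<25), overweight
   (25–29.9) and obese (≥30 kg/m²) classes; the binary analysis class merges
   overweight and obese.  T2DM+ means a positive self-reported history or use
   of insulin, metformin or a sulfonylurea, except that medication-only
   evidence is overridden to T2DM− when a GLP-1 agonist or weight-loss drug
   is also present (those are commonly prescribed for weight management
   without diabetes; a positive history always wins over the override).
   CVD+ means any of hypertension, coronary artery disease, stroke or
   dyslipidemia in the history, or any antihypertensive, lipid-lowering or
   antiplatelet/anticoagulant medication.
3. **BMI quality control.** Values outside Tukey's *outer* fences
   (Q1 − 3·IQR, Q3 + 3·IQR) are excluded in a single pass (fences computed
   once on the full input, no re-fencing).  Quartiles use Tukey hinges
   (medians of the lower/upper half, the overall median shared when n is
   odd), the convention that matches boxplot construction and is robust for
   skewed distributions.  The multiplier is a parameter; 1.5 gives the
   conventional inner fences, and inner-fence removals are provably a
   superset of outer-fence removals (tested).
4. **GRS.** Raw score = Σ risk-allele dosages over the K panel SNPs
   (0..2K); scaled score = 100·raw/(2K), reported to 2 decimals; strata are
   exact thirds of the 0–100 scale with the boundary values included in the
   outer strata — low ≤ 100/3, high ≥ 200/3, so on an 18-SNP panel low is
   raw ≤ 12 (scaled ≤ 33.33) and high is raw ≥ 24.  The inclusive-boundary
   choice is forced by the score lattice: 33.33 is an attainable value and
   the natural top of the bottom third.  Because high scores are rare under
   realistic allele frequencies, intermediate and high are merged into one
   analysis group against low.  Missing dosages: the default policy drops
   the sample (conservative); `rescale_by_available` and `mean_impute` are
   selectable and recorded in output metadata.
5. **Hardy–Weinberg.** Per SNP, allele frequency by allele counting and a
   χ² goodness-of-fit on the three genotype classes (df = 1).  Both nominal
   (α = 0.05) and Bonferroni-adjusted (α/K) significance columns are
   reported; no SNP is dropped automatically.  Monomorphic SNPs are flagged
   untestable.
6. **Association.** 2×2 tables of outcome by analysis group; cross-product
   OR with a Woolf log-method 95 % CI
   (exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))), which is identical to the Wald
   interval of a one-binary-predictor logistic model (asserted to 1e-6
   against an independent fit in the test suite).  Zero cells get the
   Haldane–Anscombe +0.5 correction, flagged; a double zero in a cross
   pattern leaves the OR undefined.  The p-value is the uncorrected Pearson
   χ² (no Yates correction — the choice that reproduces printed
   cross-product ORs at these cell sizes; a corrected variant is available
   by flag).  Fisher's exact test (two-sided, by summing hypergeometric
   probabilities ≤ that of the observed table, with a 1 + 1e-7 relative tie
   guard) replaces χ² in the descriptive table whenever an expected cell is
   below 5.  Continuous group differences use Mann–Whitney U (exact
   enumeration for tie-free samples up to n = 20, tie-corrected normal
   approximation otherwise) unless a Shapiro–Wilk check fails to reject
   normality, in which case Welch's t is used and summaries switch from
   median ± IQR to mean ± SD.
7. **Discrimination.** Each predictor is assessed alone by the AUC of a
   univariate logistic model.  Since the fitted probability of such a model
   is strictly monotone in the predictor, its ROC area equals the midrank
   (Mann–Whitney) concordance of the predictor, oriented by the sign of the
   fitted slope; and the sign of the MLE slope equals the sign of
   cov(x, y), because the score at slope 0 is proportional to it and the
   log-likelihood is concave.  The cross-validation engine exploits this:
   folds are scored by train-sign-oriented concordance, which is exactly
   the out-of-fold logistic AUC at a fraction of the cost.
   `auc_single_predictor` retains an explicit (near-unregularized sklearn)
   logistic fit, and the equivalence between the two routes is asserted to
   1e-9 over hundreds of random datasets.  The point estimate is the mean
   out-of-fold AUC over stratified 10-fold CV (stratification prevents
   single-class folds); the 95 % CI is the 2.5/97.5 percentile interval of
   that statistic over bootstrap resamples (default 1000) of the balanced
   cohort, i.e. each replicate resamples the data with replacement and
   recomputes the full CV-mean.  Bootstrapping the data rather than the
   fold AUCs is the standard bias-aware reading; the constant predictor
   scores 0.5 by the tie convention.
8. **Class balancing.** Disease outcomes: random downsampling of the
   majority class to the minority size, without replacement, seeded.  The
   BMI outcome, whose classes differ sharply in age: the overweight/obese
   class is resampled toward the age distribution of the normal-weight
   class — a Gaussian N(μ, σ) is fitted to the reference class's ages and
   target members are drawn without replacement, down to the reference
   size, with importance weights ∝ N(μ, σ) density / target empirical age
   density (Gaussian KDE).  When the target class lacks support in part of
   the reference range the achieved mean/SD cannot match the fit; the
   function then warns with the achieved values rather than failing (a
   tolerance of 10 % relative on both moments defines "matched").  Without-
   replacement weighting requires the target to be at least as large as the
   reference; genuinely disjoint age ranges are a diagnostic, not an error.

## The synthetic cohort generator

No raw records of the kind this analysis consumes are publicly available,
so the generator is a first-class module that emulates the statistical
structure the analysis assumes, and every downstream stage is tested
against it.

* **Genotypes.**  Independent Binomial(2, f) dosages per SNP — exact HWE,
  no linkage disequilibrium, no population structure.  Default frequencies
  spread linearly over 0.22–0.61 (mean 5/12), placing the expected raw
  score at ~15 of 36 (scaled median 41.67, IQR ≈ 11) and the low-GRS group
  at ~20 % of the cohort.
* **Demographics.**  Sex is assigned with a fixed margin — exactly
  round(n·0.754) females, permuted — because the female fraction is a
  design target of the emulation rather than an estimand; smoking is
  Bernoulli(0.248).  Age is truncated-normal (μ = 41, σ = 8.6, range
  18–80), giving median ≈ 41 and IQR ≈ 11.6.
* **BMI.**  Shifted lognormal: BMI = 17 + exp(2.358 + 0.022·(age − 41)
  + 0.0035·(raw GRS − E[raw]) + 0.482·Z).  The location/scale pair was
  solved analytically from two targets — mean 29.09 kg/m² and
  P(BMI ≥ 25) = 0.705 — for the age-marginal distribution (total log-scale
  SD 0.518); the age coefficient creates the age–BMI confounding gradient
  (Spearman ρ ≈ 0.35) and the small GRS coefficient keeps the group BMI
  difference under ~0.5 kg/m², i.e. not individually significant at the
  study size.  The heavy tail is on the right: a distribution with mean
  29.09 and 70 % of its mass above 25 cannot have a left-side heavy tail,
  but the `skew` parameter exposes the mirrored variant for sensitivity
  work.  Weight and height are back-computed (height normal by sex,
  rounded to questionnaire precision), so re-deriving BMI downstream
  reproduces the latent value up to rounding.
* **Outcomes.**  Bernoulli on a logistic scale:
  logit p = c + β_stratum·1[group = intermediate/high]
  + β_BMI·(BMI − 29.1) + β_age·(age − 41).  β_stratum defaults to ln 1.56
  for both outcomes; the intercept c is calibrated at generation time by
  root-finding so that the realized low-group covariates give exactly the
  configured baseline prevalence (T2DM 0.037, CVD 0.176 — the low-group
  rates implied by the overall 5.4 %/23.9 % targets), making the marginal
  prevalences land on target without hand-tuned constants.  Covariate
  coefficients (BMI 0.09 on both; age 0.05/0.08 for T2DM/CVD) were chosen
  so age and BMI dominate the discrimination ranking, as expected
  epidemiologically.  A per-allele genetic effect is available as an
  alternative to the stratum-level default.  Note the non-collapsibility
  caveat: with non-zero covariate effects the *marginal* cross-product OR
  is attenuated below the conditional ln 1.56 by roughly 5–10 %; recovery
  tests that target 1.56 exactly therefore use the covariate-free model.
* **History and medications.**  Sampled *after* the statuses,
  conditionally on them, so rule-based classification recovers the latent
  statuses exactly: T2DM+ individuals get a history flag (60 %) or a
  glucose-lowering medication; CVD+ individuals get 1–2 condition flags
  (70 %) or a cardiovascular medication; 0.5 % of T2DM− individuals carry a
  GLP-1 drug (half also metformin) to exercise the override rule.  The
  generator does not model misreporting, comorbidity correlations beyond
  the shared BMI/age terms, or medication without indication.

**What passing tests do and do not show.**  The generator reproduces the
marginal descriptives, the stratum-level effect structure and the
confounding pattern of the emulated study; it does not carry LD, population
stratification, self-report error or unmodelled covariates.  Green tests
demonstrate that the estimation machinery is correct and calibrated under
the stated data-generating process — not that the published cohort's
effect sizes are externally valid.

## Numerical and design choices

* Stratum boundaries compared with a 1e-9 tolerance on the 0–100 scale so
  attainable lattice values (33.33, 66.67) land in the outer strata after
  2-decimal rounding.
* Bootstrap CIs are percentile; the point estimate is clipped into the CI
  in the rare replicate where the percentile interval misses it.
* All randomness flows from `numpy.random.default_rng` seeds; the pipeline
  derives one child seed per discrimination task from the run seed
  (`SeedSequence.spawn`), and every report embeds the seeds, the panel
  SHA-256 and the package version.  Identical config ⇒ byte-identical
  reports.
* Problem sizes in the test suite: parameter recovery uses 200 cohorts of
  n = 4279, type-I-error calibration 1000 study-sized replicates,
  null-predictor bootstrap calibration 200 runs of n = 2000 with 100
  bootstrap replicates — sizes chosen to keep Monte-Carlo error well inside
  the asserted bands while the whole suite runs in a few minutes.
* The shipped default panel's risk alleles are curated from the external
  GWAS/nutrigenetics literature (the panel's published description lists
  genes and rsIDs only); they are configuration, not ground truth, and
  analyses of real data should review them.  All tests construct explicit
  panels.

## Known limitations

* Odds ratios are unadjusted cross-products; no multivariable or
  covariate-adjusted models are fitted, so printed CIs from adjusted
  analyses elsewhere will not match the Woolf intervals.
* The Fisher/χ² selection rule (expected cell < 5) and the normality-based
  summary switch are conventions; both are recorded per row in the output.
* `gaussian_age_match` assumes the target class covers the reference age
  range; with disjoint supports it warns and delivers the achievable
  overlap.
* VCF input handles biallelic records matched by ID only; no liftover,
  strand flipping or imputation.
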