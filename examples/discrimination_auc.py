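"""Single-predictor AUCs for CVD with class balancing, CV and bootstrap.

The CVD- majority is downsampled to the CVD+ size, then each predictor's
univariate logistic AUC is estimated as the mean out-of-fold AUC over
stratified 10-fold CV, with a percentile bootstrap 95% CI.
"""

from cardiogrs import default_panel, discrimination, emulate_study, grs_engine, phenotyping

cohort = emulate_study(seed=1)
ph = phenotyping.classify_cohort(cohort.phenotypes)
grs = grs_engine.score_cohort(cohort.genotypes, default_panel())
df = ph.join(grs, how="inner")
df["sex"] = (df["sex"] == "F").astype(float)
df["smoking"] = df["smoking"].astype(float)

balance = discrimination.BalanceSpec(method="downsample")
print(f"{'predictor':<10} {'AUC':>6} {'95% CI':>16}")
for predictor, label in (("scaled", "GRS"), ("age", "age"), ("bmi", "BMI"),
                         ("sex", "sex"), ("smoking", "smoking")):
    rep = discrimination.cv_bootstrap_auc(
        df, predictor, "cvd", balance, n_folds=10, n_boot=200, seed=7
    )
    print(f"{label:<10} {rep.auc:>6.3f} [{rep.ci_low:.3f}, {rep.ci_high:.3f}]")

print("\nAUC 0.5 is chance. Age and BMI carry most of the signal; the GRS")
print("adds a modest increment, as expected for an 18-SNP unweighted score.")
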