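"""Odds ratios for overweight/obesity, T2DM and CVD by GRS group.

Each outcome is cross-tabulated against the merged analysis group
(intermediate/high vs low GRS); the cross-product OR with a Woolf 95% CI and
the uncorrected Pearson chi-square p-value summarise the association.
"""

from cardiogrs import association_stats, default_panel, emulate_study, grs_engine, phenotyping

cohort = emulate_study(seed=1)
ph = phenotyping.classify_cohort(cohort.phenotypes)
grs = grs_engine.score_cohort(cohort.genotypes, default_panel())
df = ph.join(grs, how="inner")
df["overweight_obese"] = df["bmi_class"] == "overweight_obese"

print(f"{'outcome':<18} {'OR':>5} {'95% CI':>14} {'p':>9}")
for outcome in ("overweight_obese", "t2dm", "cvd"):
    t = association_stats.table_from_cohort(df, outcome)
    r = association_stats.odds_ratio(t)
    print(f"{outcome:<18} {r.or_estimate:>5.2f} "
          f"[{r.ci_low:.2f}, {r.ci_high:.2f}] {r.p_value:>9.2e}")

print("\nThe generator's true stratum effect is OR 1.56 on T2DM and CVD;")
print("estimates scatter around it (slightly attenuated by the BMI/age")
print("terms in the outcome model) within the 2x2-table sampling error.")
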