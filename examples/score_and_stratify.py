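"""Score a cohort with the unweighted 18-SNP GRS and check per-SNP HWE.

The raw score counts risk alleles (0..36), is rescaled to 0-100, and split
into thirds of the scale; because high scores are rare, the analysis merges
the intermediate and high strata against low.
"""

from cardiogrs import default_panel, emulate_study, grs_engine

panel = default_panel()
cohort = emulate_study(seed=1, n=2000)
grs = grs_engine.score_cohort(cohort.genotypes, panel)

print(f"panel size K = {panel.K}, raw score range 0..{panel.max_raw_score}")
print(f"median scaled GRS:  {grs['scaled'].median():.2f}")
print("stratum counts:")
print(grs["stratum"].value_counts().to_string())
print("analysis groups:")
print(grs["analysis_group"].value_counts().to_string())

hwe = grs_engine.hwe_scan(cohort.genotypes, panel)
n_flagged = int(hwe["significant_bonferroni"].sum())
print(f"\nHWE: {n_flagged} of {panel.K} SNPs flagged at the Bonferroni level")
print("(genotypes are drawn in Hardy-Weinberg proportions, so flags are rare)")
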