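"""End-to-end orchestration: QC -> GRS -> associations -> discrimination.

``run_pipeline`` takes a :class:`RunConfig`, either simulating a cohort or
loading genotype/phenotype files, and writes a machine-readable report
bundle:

* ``cohort_flow.json`` — inclusion/exclusion bookkeeping per reason;
* ``table2.tsv`` — descriptive characteristics by analysis group;
* ``forest_or.tsv`` — odds ratios (95% CI, p) for overweight/obesity, T2DM
  and CVD, intermediate/high- vs low-GRS;
* ``auc_report.tsv`` — per-predictor AUC with bootstrap CIs per outcome;
* ``hwe.tsv`` — per-SNP Hardy-Weinberg results;
* ``run_log.json`` — config echo, derived seeds, panel checksum, version.

Every stochastic stage draws its seed from the config seed, so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association_stats, discrimination, grs_engine, phenotyping
from .panel_io import (
    GenotypeMatrix,
    SNPPanel,
    assemble_cohort,
    default_panel,
    load_panel,
    read_phenotypes,
)
from .synthetic_cohort import STUDY_N, CohortSpec, generate


@dataclass
class RunConfig:
    out_dir: str | Path = "cardiogrs_run"
    seed: int = 1
    # simulation (used when no input paths are given)
    n: int = STUDY_N
    # input paths (genotypes: .tsv dosage dialect or .vcf)
    genotypes_path: str | Path | None = None
    phenotypes_path: str | Path | None = None
    panel_path: str | Path | None = None
    med_map_path: str | Path | None = None
    missing_policy: str = "exclude"
    tukey_multiplier: float = 3.0
    n_folds: int = 10
    n_boot: int = 1000
    balance: str = "downsample"  # for disease outcomes; BMI uses age matching
    outcomes: tuple[str, ...] = ("overweight_obese", "t2dm", "cvd")
    predictors: tuple[str, ...] = ("scaled", "age", "bmi", "sex", "smoking")


def _panel_checksum(panel: SNPPanel) -> str:
    blob = "\n".join(f"{s.rsid}\t{s.gene_label}\t{s.risk_allele}" for s in panel.snps)
    return hashlib.sha256(blob.encode()).hexdigest()


def _load_inputs(config: RunConfig, panel: SNPPanel):
    if config.genotypes_path is None:
        cohort = generate(CohortSpec(n=config.n, panel=panel, seed=config.seed))
        return cohort.genotypes, cohort.phenotypes
    gpath = Path(config.genotypes_path)
    if gpath.suffix.lower() in (".vcf", ".gz", ".bcf"):
        genotypes = GenotypeMatrix.from_vcf(gpath, panel)
    else:
        genotypes = GenotypeMatrix.from_tsv(gpath, panel)
    phenotypes = read_phenotypes(config.phenotypes_path)
    return genotypes, phenotypes


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the in-memory
    results keyed by report name."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = load_panel(config.panel_path) if config.panel_path else default_panel()
    med_map = phenotyping.load_medication_map(config.med_map_path)
    seed_seq = np.random.SeedSequence(config.seed)
    # one derived child seed per discrimination (outcome, predictor) pair
    child_seeds = iter(seed_seq.spawn(512))

    genotypes, phenotypes = _load_inputs(config, panel)
    assembly = assemble_cohort(genotypes, phenotypes)

    pheno = phenotyping.classify_cohort(assembly.phenotypes, med_map)
    mask, fences = phenotyping.tukey_outlier_mask(
        pheno["bmi"].to_numpy(), config.tukey_multiplier
    )
    outlier_ids = list(pheno.index[mask])
    assembly = assembly.exclude(outlier_ids, "bmi_outlier")
    pheno = pheno.loc[assembly.included_ids]

    grs = grs_engine.score_cohort(assembly.genotypes, panel, config.missing_policy)
    cohort = pheno.join(grs, how="inner")
    cohort["overweight_obese"] = cohort["bmi_class"] == "overweight_obese"

    hwe = grs_engine.hwe_scan(assembly.genotypes, panel)
    table2 = association_stats.descriptive_table(cohort)

    forest_rows = []
    for outcome in config.outcomes:
        t = association_stats.table_from_cohort(cohort, outcome)
        orr = association_stats.odds_ratio(t)
        chi2, p_chi = association_stats.chi_square_test(t)
        forest_rows.append(
            {
                "outcome": outcome,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "or": round(orr.or_estimate, 2),
                "ci_low": round(orr.ci_low, 2),
                "ci_high": round(orr.ci_high, 2),
                "chi2": chi2,
                "p": p_chi,
                "method": orr.method,
                "haldane_corrected": orr.haldane_corrected,
            }
        )
    forest = pd.DataFrame(forest_rows)

    work = cohort.copy()
    work["sex"] = (work["sex"] == "F").astype(float)
    work["smoking"] = work["smoking"].astype(float)
    auc_rows = []
    for outcome in config.outcomes:
        if outcome == "overweight_obese":
            balance = discrimination.BalanceSpec(
                method="gaussian_age_match", reference_class=False
            )
        else:
            balance = discrimination.BalanceSpec(method=config.balance)
        extra = [o for o in ("t2dm", "cvd") if o != outcome and o in work.columns]
        for predictor in list(config.predictors) + extra:
            if predictor == outcome:
                continue
            child = next(child_seeds)
            rep = discrimination.cv_bootstrap_auc(
                work.assign(**{outcome: work[outcome].astype(bool)}),
                predictor={"scaled": "scaled"}.get(predictor, predictor),
                outcome=outcome,
                balance=balance,
                n_folds=config.n_folds,
                n_boot=config.n_boot,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            auc_rows.append(dataclasses.asdict(rep))
    auc_report = pd.DataFrame(auc_rows)

    flow = {
        "n_input": assembly.n_input,
        "n_included": len(assembly.included_ids),
        "n_scored": len(cohort),
        "exclusions": assembly.exclusion_counts(),
        "grs_missing_excluded": grs.attrs.get("excluded_missing", []),
        "bmi_fences": {
            "q1": fences.q1, "q3": fences.q3, "iqr": fences.iqr,
            "lower": fences.lower_fence, "upper": fences.upper_fence,
            "multiplier": fences.multiplier,
        },
    }
    log = {
        "version": __version__,
        "panel_sha256": _panel_checksum(panel),
        "panel_K": panel.K,
        "seed": config.seed,
        "missing_policy": config.missing_policy,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }

    (out_dir / "cohort_flow.json").write_text(json.dumps(flow, indent=2))
    table2.to_csv(out_dir / "table2.tsv", sep="\t", index=False)
    forest.to_csv(out_dir / "forest_or.tsv", sep="\t", index=False)
    auc_report.to_csv(out_dir / "auc_report.tsv", sep="\t", index=False)
    hwe.to_csv(out_dir / "hwe.tsv", sep="\t")
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))

    return {
        "cohort": cohort,
        "cohort_flow": flow,
        "table2": table2,
        "forest_or": forest,
        "auc_report": auc_report,
        "hwe": hwe,
        "run_log": log,
    }
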