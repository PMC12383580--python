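"""SNP panel definition, genotype/phenotype input, and cohort assembly.

The analysis operates on a small fixed panel of biallelic SNPs, each with a
configured *risk allele*.  Genotypes are represented as per-sample risk-allele
dosages (0, 1, 2 or missing).  Risk alleles are configuration: association
panels of this kind are published as gene/rsID lists, and the adverse allele
for each variant has to be curated from the primary literature.  The shipped
``default_panel.tsv`` carries one such curation for the 18-SNP cardiometabolic
panel; any analysis can substitute its own panel file.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: marker used for uncalled dosages in the tabular dialect
MISSING = "NA"

HISTORY_FLAGS = frozenset(
    {"t2dm", "hypertension", "coronary_artery_disease", "stroke", "dyslipidemia"}
)


class PanelConfigError(ValueError):
    """Raised for malformed panel configuration (duplicate rsid, bad allele...)."""


@dataclass(frozen=True)
class SNPDef:
    """One biallelic SNP of the panel, with its configured risk allele."""

    rsid: str
    risk_allele: str
    gene_label: str = ""
    ref_alt_context: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.risk_allele not in VALID_ALLELES:
            raise PanelConfigError(
                f"{self.rsid}: risk allele {self.risk_allele!r} is not one of A/C/G/T"
            )


@dataclass(frozen=True)
class SNPPanel:
    """Ordered SNP panel; the maximum attainable raw score is ``2 * K``."""

    snps: tuple[SNPDef, ...]

    def __post_init__(self) -> None:
        rsids = [s.rsid for s in self.snps]
        if len(rsids) == 0:
            raise PanelConfigError("panel must contain at least one SNP")
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise PanelConfigError(f"duplicate rsid(s) in panel: {sorted(dupes)}")

    @property
    def K(self) -> int:
        return len(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    @property
    def max_raw_score(self) -> int:
        return 2 * self.K

    def risk_allele(self, rsid: str) -> str:
        for s in self.snps:
            if s.rsid == rsid:
                return s.risk_allele
        raise KeyError(rsid)


def load_panel(path: str | Path) -> SNPPanel:
    """Read a panel config (JSON list of objects, or TSV with header
    ``rsid``/``gene``/``risk_allele``), preserving file order."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
        snps = [
            SNPDef(
                rsid=e["rsid"],
                risk_allele=e["risk_allele"],
                gene_label=e.get("gene", e.get("gene_label", "")),
            )
            for e in entries
        ]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"rsid", "risk_allele"}
        if not required.issubset(df.columns):
            raise PanelConfigError(f"panel file must have columns {sorted(required)}")
        gene_col = "gene" if "gene" in df.columns else None
        snps = [
            SNPDef(
                rsid=row["rsid"],
                risk_allele=row["risk_allele"],
                gene_label=row[gene_col] if gene_col else "",
            )
            for _, row in df.iterrows()
        ]
    return SNPPanel(tuple(snps))


def default_panel() -> SNPPanel:
    """The shipped 18-SNP cardiometabolic/nutrigenetic panel.

    Risk alleles are curated defaults from the external GWAS literature (the
    source gene/rsID list does not fix them) and should be reviewed before
    use on real genotype data.
    """
    with resources.as_file(
        resources.files("cardiogrs.data") / "default_panel.tsv"
    ) as p:
        return load_panel(p)


def risk_allele_dosage(genotype: str | None, risk_allele: str) -> float:
    """Count of the risk allele in a genotype string such as ``"AT"``.

    Uncalled genotypes (``None``, ``""``, ``"./."``, ``"NN"``) map to NaN.
    """
    if genotype is None:
        return np.nan
    g = genotype.strip().upper().replace("/", "").replace("|", "")
    if g in ("", "..", "NN", MISSING):
        return np.nan
    if len(g) != 2 or any(a not in VALID_ALLELES for a in g):
        raise ValueError(f"uninterpretable genotype {genotype!r}")
    return float(sum(a == risk_allele for a in g))


@dataclass
class GenotypeMatrix:
    """Per-sample risk-allele dosages for a panel, column order = panel order.

    Backed by a float DataFrame (index: sample ids, columns: rsids) with NaN
    as the missing marker; stored values are validated to be 0, 1 or 2.
    """

    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def n_samples(self) -> int:
        return len(self.dosages)

    def to_tsv(self, path: str | Path) -> None:
        out = self.dosages.copy()
        # keep called dosages as integers in the text dialect
        out = out.map(lambda v: "" if pd.isna(v) else str(int(v)))
        out.replace("", MISSING).to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, panel: SNPPanel) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=[MISSING])
        df.index = df.index.astype(str)
        missing_cols = [r for r in panel.rsids if r not in df.columns]
        for r in missing_cols:
            warnings.warn(f"panel SNP {r} absent from genotype file; column set to missing")
            df[r] = np.nan
        return cls(df[panel.rsids].astype(float))

    @classmethod
    def from_vcf(cls, path: str | Path, panel: SNPPanel) -> "GenotypeMatrix":
        """Read panel SNPs from a VCF, matching records by the ID column.

        The configured risk allele must be the REF or the (single) ALT allele
        of the matched record; multi-allelic records are rejected.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        data: dict[str, np.ndarray] = {}
        wanted = {s.rsid: s for s in panel.snps}
        for variant in vcf:
            snp = wanted.get(variant.ID)
            if snp is None:
                continue
            alts = [a for a in variant.ALT if a != "."]
            if len(alts) > 1:
                raise ValueError(f"{snp.rsid}: multi-allelic VCF record not supported")
            alleles = [variant.REF] + alts
            if snp.risk_allele not in alleles:
                raise ValueError(
                    f"{snp.rsid}: configured risk allele {snp.risk_allele} matches "
                    f"neither REF ({variant.REF}) nor ALT ({alts or ['-']})"
                )
            risk_idx = alleles.index(snp.risk_allele)
            gts = np.asarray(variant.genotypes, dtype=object)
            col = np.full(len(samples), np.nan)
            for i, gt in enumerate(gts):
                a1, a2 = int(gt[0]), int(gt[1])
                if a1 < 0 or a2 < 0:
                    continue
                col[i] = float((a1 == risk_idx) + (a2 == risk_idx))
            data[snp.rsid] = col
        df = pd.DataFrame(index=pd.Index(samples, name="sample_id", dtype=str))
        for rsid in panel.rsids:
            if rsid not in data:
                warnings.warn(f"panel SNP {rsid} absent from VCF; column set to missing")
                df[rsid] = np.nan
            else:
                df[rsid] = data[rsid]
        return cls(df)


@dataclass
class PhenotypeRecord:
    """One questionnaire record."""

    sample_id: str
    age: float
    sex: str  # "M" | "F"
    weight: float  # kg
    height: float  # m
    smoking: bool
    history_flags: frozenset[str] = field(default_factory=frozenset)
    medications: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.age <= 0 or self.weight <= 0 or self.height <= 0:
            raise ValueError(
                f"{self.sample_id}: age, weight and height must be positive"
            )


def _parse_labels(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    if isinstance(cell, frozenset):
        return cell
    return frozenset(x.strip() for x in str(cell).split(";") if x.strip())


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype CSV.

    Expected header: ``sample_id,age,sex,weight_kg,height_m,smoking,history,
    medications`` where history/medications are semicolon-separated label
    lists.  Returns a DataFrame indexed by sample_id with ``history`` and
    ``medications`` as frozensets and ``smoking`` as bool.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    df = df.set_index("sample_id")
    df = df.rename(columns={"weight_kg": "weight", "height_m": "height"})
    df["smoking"] = (
        df["smoking"].astype(str).str.strip().str.lower().isin(("yes", "true", "1"))
    )
    df["history"] = df.get("history", pd.Series(index=df.index, dtype=object)).map(
        _parse_labels
    )
    df["medications"] = df.get(
        "medications", pd.Series(index=df.index, dtype=object)
    ).map(_parse_labels)
    for col in ("age", "weight", "height"):
        if (df[col] <= 0).any():
            bad = df.index[df[col] <= 0].tolist()
            raise ValueError(f"non-positive {col} for sample(s) {bad}")
    return df


def phenotypes_to_records(df: pd.DataFrame) -> list[PhenotypeRecord]:
    return [
        PhenotypeRecord(
            sample_id=str(sid),
            age=row["age"],
            sex=row["sex"],
            weight=row["weight"],
            height=row["height"],
            smoking=bool(row["smoking"]),
            history_flags=row["history"],
            medications=row["medications"],
        )
        for sid, row in df.iterrows()
    ]


@dataclass
class CohortAssembly:
    """Join of genotype and questionnaire data with exclusion bookkeeping.

    Every input sample is either included or excluded with exactly one
    primary reason (``missing_questionnaire``, ``missing_genotype``,
    ``bmi_outlier``); conservation |included| + |excluded| = |input| holds
    at every stage.
    """

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # indexed by sample_id, included samples only
    excluded: pd.DataFrame  # columns: sample_id, reason

    @property
    def included_ids(self) -> list[str]:
        return list(self.phenotypes.index)

    @property
    def n_input(self) -> int:
        return len(self.phenotypes) + len(self.excluded)

    def exclusion_counts(self) -> dict[str, int]:
        counts = {"missing_questionnaire": 0, "missing_genotype": 0, "bmi_outlier": 0}
        counts.update(self.excluded["reason"].value_counts().to_dict())
        return counts

    def exclude(self, sample_ids: Sequence[str], reason: str) -> "CohortAssembly":
        """Return a new assembly with the given included samples moved to the
        excluded set under ``reason``."""
        ids = [s for s in sample_ids if s in self.phenotypes.index]
        new_excl = pd.concat(
            [
                self.excluded,
                pd.DataFrame({"sample_id": ids, "reason": reason}),
            ],
            ignore_index=True,
        )
        keep = self.phenotypes.index.difference(ids)
        keep = [s for s in self.phenotypes.index if s in set(keep)]  # preserve order
        return CohortAssembly(
            genotypes=GenotypeMatrix(self.genotypes.dosages.loc[keep]),
            phenotypes=self.phenotypes.loc[keep],
            excluded=new_excl,
        )


def assemble_cohort(
    genotypes: GenotypeMatrix, phenotypes: pd.DataFrame
) -> CohortAssembly:
    """Intersect genotyped and questionnaire samples (exact string match).

    Samples with genotypes but no questionnaire are excluded with reason
    ``missing_questionnaire`` and vice versa.  Raises if the intersection is
    empty.  BMI-outlier exclusion is applied afterwards via
    :meth:`CohortAssembly.exclude` (see :mod:`cardiogrs.phenotyping`).
    """
    geno_ids = list(genotypes.dosages.index)
    pheno_ids = list(phenotypes.index)
    common = [s for s in geno_ids if s in set(pheno_ids)]
    if not common:
        raise ValueError("no samples have both genotype and questionnaire data")
    excluded_rows = [
        {"sample_id": s, "reason": "missing_questionnaire"}
        for s in geno_ids
        if s not in set(pheno_ids)
    ] + [
        {"sample_id": s, "reason": "missing_genotype"}
        for s in pheno_ids
        if s not in set(geno_ids)
    ]
    return CohortAssembly(
        genotypes=GenotypeMatrix(genotypes.dosages.loc[common]),
        phenotypes=phenotypes.loc[common],
        excluded=pd.DataFrame(excluded_rows, columns=["sample_id", "reason"]),
    )
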