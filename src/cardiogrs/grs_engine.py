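"""Additive genetic risk score, 0-100 rescaling, tertile strata, HWE tests.

The unweighted GRS counts risk alleles over the panel: each SNP contributes
0, 1 or 2 points, so an 18-SNP panel spans 0..36 raw points.  For
interpretability the raw count is rescaled to 0-100 (``100 * raw / 2K``) and
stratified into thirds of the scale: low (<= 100/3), intermediate, high
(>= 200/3).  The thirds are exact fractions with the boundary values included
in the outer strata — on an 18-SNP panel 33.33 (raw 12) is the top of the low
stratum and 66.67 (raw 24) the bottom of the high stratum.  Because high-GRS
individuals are rare on realistic allele frequencies, the analysis group
merges intermediate and high against low.

Per-SNP Hardy-Weinberg equilibrium is checked with the chi-square
goodness-of-fit test on the three genotype classes (df = 1, allele frequency
estimated by allele counting).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import GenotypeMatrix, SNPPanel

_THIRD = 100.0 / 3.0
_EPS = 1e-9

MissingPolicy = Literal["exclude", "rescale_by_available", "mean_impute"]


@dataclass(frozen=True)
class GRSResult:
    raw: float  # risk-allele count (integer unless imputed)
    scaled: float  # 0-100, two decimals
    stratum: str  # low | intermediate | high
    analysis_group: str  # low | intermediate_high
    n_missing_snps: int = 0


def rescale(raw: float, K: int) -> float:
    """Transform a 0..2K risk-allele count to the 0-100 scale (2 decimals)."""
    if K < 1:
        raise ValueError("panel size K must be >= 1")
    if not 0 <= raw <= 2 * K:
        raise ValueError(f"raw score {raw} outside [0, {2 * K}]")
    return round(100.0 * raw / (2 * K), 2)


def stratify(scaled: float) -> tuple[str, str]:
    """Stratum and merged analysis group for a 0-100 score.

    Cut points are exact thirds of the scale; the boundary scores 100/3 and
    200/3 belong to the low and high strata respectively.
    """
    if not 0 <= scaled <= 100:
        raise ValueError(f"scaled score {scaled} outside [0, 100]")
    if scaled <= _THIRD + _EPS:
        return "low", "low"
    if scaled >= 2 * _THIRD - _EPS:
        return "high", "intermediate_high"
    return "intermediate", "intermediate_high"


def raw_grs(
    dosages: Sequence[float],
    panel: SNPPanel,
    missing_policy: MissingPolicy = "exclude",
    snp_means: Sequence[float] | None = None,
) -> GRSResult | None:
    """Score a single sample's dosage vector (panel order).

    Missing dosages are handled per ``missing_policy``:

    * ``exclude`` (default) — any missing SNP drops the sample (returns None);
    * ``rescale_by_available`` — score over called SNPs, rescaled to the
      full 0-100 range by the number available;
    * ``mean_impute`` — missing dosages replaced by the per-SNP cohort mean
      (``snp_means`` must be provided).

    A sample with all SNPs missing is always excluded.
    """
    x = np.asarray(dosages, dtype=float)
    if len(x) != panel.K:
        raise ValueError(f"expected {panel.K} dosages, got {len(x)}")
    miss = np.isnan(x)
    n_missing = int(miss.sum())
    if n_missing == panel.K:
        return None
    if n_missing == 0:
        raw = float(x.sum())
        scaled = rescale(raw, panel.K)
    elif missing_policy == "exclude":
        return None
    elif missing_policy == "rescale_by_available":
        avail = panel.K - n_missing
        raw = float(np.nansum(x))
        scaled = round(100.0 * raw / (2 * avail), 2)
    elif missing_policy == "mean_impute":
        if snp_means is None:
            raise ValueError("mean_impute requires snp_means")
        filled = np.where(miss, np.asarray(snp_means, dtype=float), x)
        raw = float(filled.sum())
        scaled = round(100.0 * raw / (2 * panel.K), 2)
    else:
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    stratum, group = stratify(scaled)
    return GRSResult(raw, scaled, stratum, group, n_missing)


def score_cohort(
    genotypes: GenotypeMatrix,
    panel: SNPPanel,
    missing_policy: MissingPolicy = "exclude",
) -> pd.DataFrame:
    """Per-sample GRS table: raw, scaled, stratum, analysis_group, n_missing.

    Samples dropped by the missing policy are absent from the result (their
    ids are recorded in the frame's ``attrs['excluded_missing']``).
    """
    dos = genotypes.dosages[panel.rsids]
    means = dos.mean(axis=0, skipna=True).to_numpy()
    rows, dropped = {}, []
    for sid, vec in zip(dos.index, dos.to_numpy()):
        res = raw_grs(vec, panel, missing_policy, snp_means=means)
        if res is None:
            dropped.append(sid)
        else:
            rows[sid] = (res.raw, res.scaled, res.stratum, res.analysis_group,
                         res.n_missing_snps)
    out = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["raw", "scaled", "stratum", "analysis_group", "n_missing"],
    )
    out.index.name = "sample_id"
    out.attrs["missing_policy"] = missing_policy
    out.attrs["excluded_missing"] = dropped
    return out


@dataclass(frozen=True)
class HWEResult:
    n_hom_ref: int
    n_het: int
    n_hom_risk: int
    p_hat: float  # estimated risk-allele frequency
    expected: tuple[float, float, float]
    chi2: float
    p_value: float
    testable: bool = True


def hwe_test(genotype_counts: tuple[int, int, int]) -> HWEResult:
    """Chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    ``genotype_counts`` are (hom non-risk, het, hom risk).  The risk-allele
    frequency is estimated by allele counting; expected class counts are
    n*q^2, 2n*p*q, n*p^2.  Monomorphic SNPs are flagged untestable (chi2 and
    p are NaN) rather than dividing by zero.
    """
    n00, n01, n11 = (int(c) for c in genotype_counts)
    if min(n00, n01, n11) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n00 + n01 + n11
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (n01 + 2 * n11) / (2 * n)
    q = 1.0 - p
    if p <= 0.0 or p >= 1.0:
        return HWEResult(n00, n01, n11, p, (n * q**2, 2 * n * p * q, n * p**2),
                         float("nan"), float("nan"), testable=False)
    expected = (n * q**2, 2 * n * p * q, n * p**2)
    chi2 = sum((o - e) ** 2 / e for o, e in zip((n00, n01, n11), expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(n00, n01, n11, p, expected, float(chi2), p_value)


def hwe_scan(
    genotypes: GenotypeMatrix, panel: SNPPanel, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-SNP HWE table with nominal and Bonferroni-adjusted significance.

    No SNP is dropped automatically; both columns are reported so review
    stays a human decision.
    """
    rows = []
    bonf = alpha / panel.K
    for rsid in panel.rsids:
        col = genotypes.dosages[rsid].dropna().to_numpy()
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        r = hwe_test(counts) if sum(counts) > 0 else None
        if r is None:
            rows.append({"rsid": rsid, "n": 0, "testable": False})
            continue
        rows.append(
            {
                "rsid": rsid,
                "n": sum(counts),
                "n_hom_ref": r.n_hom_ref,
                "n_het": r.n_het,
                "n_hom_risk": r.n_hom_risk,
                "risk_allele_freq": r.p_hat,
                "chi2": r.chi2,
                "p_value": r.p_value,
                "testable": r.testable,
                f"significant_{alpha}": bool(r.testable and r.p_value < alpha),
                "significant_bonferroni": bool(r.testable and r.p_value < bonf),
            }
        )
    return pd.DataFrame(rows).set_index("rsid")
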