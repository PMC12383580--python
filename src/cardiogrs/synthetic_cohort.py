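"""Synthetic case-control cohorts with the structure the analysis assumes.

The generator emulates a questionnaire + genotyping study of adults enriched
for weight-management clients: ~75% female, median age ~41 years, a
right-tailed BMI distribution with mean ~29.1 kg/m2 of which ~70% fall in
the overweight/obese range, an age-BMI confounding gradient, T2DM prevalence
~5.4% and CVD-trait prevalence ~23.9%, and a stratum-level genetic effect of
OR 1.56 (intermediate/high- vs low-GRS) on both disease outcomes.

Genotypes are drawn per SNP as independent Binomial(2, freq) — i.e. exact
Hardy-Weinberg proportions with no linkage disequilibrium.  BMI is a shifted
lognormal whose location moves with age and (weakly) with the risk-allele
count; its parameters were solved from the target mean (29.09) and
overweight/obese fraction (0.705).  Disease statuses are Bernoulli draws on
a logistic scale; the intercept is calibrated at generation time by
root-finding so that the realized low-GRS-group covariates reproduce the
configured baseline prevalence, and the stratum effect enters as a log-OR
(a per-allele alternative is available for sensitivity analyses).  History
flags and medication labels are then sampled consistently with the drawn
statuses, including a configurable fraction of disease-negative GLP-1 users
so the phenotyping override rules are exercised.

Everything is driven by one seeded NumPy generator: identical spec + seed
gives bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .panel_io import GenotypeMatrix, SNPPanel, default_panel

STUDY_N = 4279  # analysis-ready cohort size after QC exclusions


@dataclass(frozen=True)
class AgeModel:
    loc: float = 41.0
    scale: float = 8.6  # ~ IQR 11.6 for a normal
    low: float = 18.0
    high: float = 80.0


@dataclass(frozen=True)
class BmiModel:
    """Shifted-lognormal BMI: bmi = offset + exp(loc + effects + noise).

    Defaults solve mean 29.09 kg/m2 and P(bmi >= 25) = 0.705 for the
    age-marginal distribution.  ``skew`` selects the heavy-tail side; the
    default right tail is the one consistent with a mean of 29.09 alongside
    ~70% of mass above 25 (a genuinely left-skewed BMI could not produce
    both), but the direction is exposed rather than hard-coded.
    """

    offset: float = 17.0
    log_loc: float = 2.358
    log_noise: float = 0.482
    age_coef: float = 0.022  # per year, log scale
    grs_coef: float = 0.0035  # per risk allele, log scale
    skew: str = "right"  # right | left


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome: baseline prevalence in the low-GRS group plus
    stratum-, BMI- and age-effects on the log-odds scale."""

    baseline_prev: float
    stratum_log_or: float = math.log(1.56)
    bmi_log_or: float = 0.0
    age_log_or: float = 0.0
    per_allele: bool = False
    allele_log_or: float = 0.0


def default_freqs(K: int = 18) -> np.ndarray:
    """Risk-allele frequencies spread over ~0.22-0.61 (mean 5/12), placing
    the expected raw score near 15/36 of the scale."""
    return np.linspace(0.22, 0.61, K)


@dataclass(frozen=True)
class CohortSpec:
    n: int = STUDY_N
    panel: SNPPanel = field(default_factory=default_panel)
    risk_allele_freqs: tuple[float, ...] | None = None
    female_fraction: float = 0.754
    smoking_fraction: float = 0.248
    age_model: AgeModel = AgeModel()
    bmi_model: BmiModel = BmiModel()
    t2dm_model: OutcomeModel = OutcomeModel(
        baseline_prev=0.037, bmi_log_or=0.09, age_log_or=0.05
    )
    cvd_model: OutcomeModel = OutcomeModel(
        baseline_prev=0.176, bmi_log_or=0.09, age_log_or=0.08
    )
    glp1_negative_fraction: float = 0.005  # T2DM- individuals on GLP-1 drugs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        freqs = self.freqs
        if np.any((freqs < 0) | (freqs > 1)):
            raise ValueError("risk-allele frequencies must lie in [0, 1]")
        for m in (self.t2dm_model, self.cvd_model):
            if not 0 < m.baseline_prev < 1:
                raise ValueError("baseline prevalence must lie in (0, 1)")

    @property
    def freqs(self) -> np.ndarray:
        if self.risk_allele_freqs is not None:
            return np.asarray(self.risk_allele_freqs, dtype=float)
        return default_freqs(self.panel.K)


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # read_phenotypes-format frame
    spec: CohortSpec
    latent: pd.DataFrame  # realized raw GRS, group, true statuses

    def write(self, out_prefix: str | Path) -> dict[str, Path]:
        """Write genotype TSV, phenotype CSV and ground-truth JSON."""
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": out_prefix.with_suffix(".genotypes.tsv"),
            "phenotypes": out_prefix.with_suffix(".phenotypes.csv"),
            "truth": out_prefix.with_suffix(".truth.json"),
        }
        self.genotypes.to_tsv(paths["genotypes"])
        pheno = self.phenotypes.copy()
        pheno["history"] = pheno["history"].map(lambda s: ";".join(sorted(s)))
        pheno["medications"] = pheno["medications"].map(lambda s: ";".join(sorted(s)))
        pheno = pheno.rename(columns={"weight": "weight_kg", "height": "height_m"})
        pheno["smoking"] = np.where(pheno["smoking"], "yes", "no")
        pheno.to_csv(paths["phenotypes"], index_label="sample_id")
        truth = dataclasses.asdict(self.spec)
        truth["panel"] = {"rsids": self.spec.panel.rsids}
        truth["risk_allele_freqs"] = list(map(float, self.spec.freqs))
        paths["truth"].write_text(json.dumps(truth, indent=2, default=str))
        return paths


def gen_genotypes(
    freqs, n: int, seed: int | np.random.Generator, panel: SNPPanel | None = None
) -> GenotypeMatrix:
    """Independent Binomial(2, freq) dosages per SNP (exact HWE, no LD)."""
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("risk-allele frequencies must lie in [0, 1]")
    if panel is None:
        rsids = [f"snp{i + 1}" for i in range(len(freqs))]
    else:
        if panel.K != len(freqs):
            raise ValueError("one frequency per panel SNP required")
        rsids = panel.rsids
    dosages = rng.binomial(2, freqs, size=(n, len(freqs))).astype(float)
    ids = [f"S{i + 1:06d}" for i in range(n)]
    return GenotypeMatrix(
        pd.DataFrame(dosages, index=pd.Index(ids, name="sample_id"), columns=rsids)
    )


def _truncated_normal(
    rng: np.random.Generator, loc: float, scale: float, low: float, high: float, n: int
) -> np.ndarray:
    a, b = (low - loc) / scale, (high - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)


def _calibrate_intercept(cov_lp_low: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + covariate log-odds)) = target over the
    realized low-group members."""

    def f(c: float) -> float:
        return float(np.mean(special.expit(c + cov_lp_low))) - target

    return optimize.brentq(f, -30.0, 30.0)


def _draw_status(
    rng: np.random.Generator,
    model: OutcomeModel,
    raw: np.ndarray,
    in_high_group: np.ndarray,
    bmi: np.ndarray,
    age: np.ndarray,
    bmi_ref: float,
    age_ref: float,
) -> np.ndarray:
    cov_lp = model.bmi_log_or * (bmi - bmi_ref) + model.age_log_or * (age - age_ref)
    if model.per_allele:
        genetic = model.allele_log_or * (raw - raw[~in_high_group].mean())
    else:
        genetic = model.stratum_log_or * in_high_group
    low = ~in_high_group
    if not low.any():
        raise ValueError("no low-GRS members to calibrate the baseline prevalence")
    base = cov_lp[low] + (genetic[low] if model.per_allele else 0.0)
    c = _calibrate_intercept(base, model.baseline_prev)
    p = special.expit(c + cov_lp + genetic)
    return rng.random(len(p)) < p


_CVD_FLAGS = np.array(
    ["hypertension", "dyslipidemia", "coronary_artery_disease", "stroke"]
)
_CVD_FLAG_W = np.array([0.45, 0.35, 0.12, 0.08])
_CVD_MEDS = np.array(["amlodipine", "atorvastatin", "aspirin"])
_T2DM_MEDS = np.array(["metformin", "insulin", "gliclazide"])
_T2DM_MED_W = np.array([0.7, 0.15, 0.15])


def gen_phenotypes(
    spec: CohortSpec,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Questionnaire records consistent with the genotypes.

    Returns ``(phenotypes, latent)``: the phenotype frame in the
    :func:`cardiogrs.panel_io.read_phenotypes` layout, and the latent frame
    with the realized raw score, analysis group and true statuses.
    """
    if genotypes.n_samples != spec.n:
        raise ValueError("genotype sample count must equal spec.n")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n
    K = spec.panel.K
    raw = genotypes.dosages.to_numpy().sum(axis=1)
    in_high_group = raw > (2 * K) / 3.0  # intermediate/high vs low (raw > 2K/3)

    # fixed-margin sex composition: the female fraction is a design target of
    # the emulation, so it is matched exactly (up to rounding) and shuffled,
    # rather than left to Bernoulli sampling noise
    n_female = int(round(n * spec.female_fraction))
    female = rng.permutation(np.r_[np.ones(n_female, bool),
                                   np.zeros(n - n_female, bool)])
    smoking = rng.random(n) < spec.smoking_fraction
    am = spec.age_model
    age = _truncated_normal(rng, am.loc, am.scale, am.low, am.high, n)

    bm = spec.bmi_model
    expected_raw = 2.0 * spec.freqs.sum()
    log_term = (
        bm.log_loc
        + bm.age_coef * (age - am.loc)
        + bm.grs_coef * (raw - expected_raw)
        + bm.log_noise * rng.standard_normal(n)
    )
    tail = np.exp(log_term)
    if bm.skew == "right":
        bmi = bm.offset + tail
    elif bm.skew == "left":
        # mirrored tail below a high offset; mean/median relation inverted
        bmi = (bm.offset + 2 * math.exp(bm.log_loc + bm.log_noise**2 / 2)) - tail
    else:
        raise ValueError("bmi skew must be 'right' or 'left'")
    bmi = np.maximum(bmi, 13.0)

    height = np.where(
        female,
        rng.normal(1.64, 0.06, n),
        rng.normal(1.77, 0.065, n),
    ).round(2)
    weight = (bmi * height**2).round(1)

    t2dm = _draw_status(
        rng, spec.t2dm_model, raw, in_high_group, bmi, age, 29.1, am.loc
    )
    cvd = _draw_status(
        rng, spec.cvd_model, raw, in_high_group, bmi, age, 29.1, am.loc
    )

    history: list[frozenset[str]] = []
    medications: list[frozenset[str]] = []
    u_t2dm_src = rng.random(n)
    u_t2dm_extra = rng.random(n)
    u_cvd_src = rng.random(n)
    u_cvd_extra = rng.random(n)
    u_glp1 = rng.random(n)
    t2dm_meds = rng.choice(_T2DM_MEDS, size=n, p=_T2DM_MED_W)
    cvd_flags = rng.choice(_CVD_FLAGS, size=n, p=_CVD_FLAG_W)
    cvd_flags2 = rng.choice(_CVD_FLAGS, size=n, p=_CVD_FLAG_W)
    cvd_meds = rng.choice(_CVD_MEDS, size=n)
    for i in range(n):
        hist: set[str] = set()
        meds: set[str] = set()
        if t2dm[i]:
            if u_t2dm_src[i] < 0.6:
                hist.add("t2dm")
                if u_t2dm_extra[i] < 0.5:
                    meds.add(t2dm_meds[i])
            else:
                meds.add(t2dm_meds[i])
        elif u_glp1[i] < spec.glp1_negative_fraction:
            meds.add("semaglutide")
            if u_t2dm_extra[i] < 0.5:
                # co-prescribed metformin: still T2DM- under the override rule
                meds.add("metformin")
        if cvd[i]:
            if u_cvd_src[i] < 0.7:
                hist.add(cvd_flags[i])
                if u_cvd_extra[i] < 0.2:
                    hist.add(cvd_flags2[i])
            else:
                meds.add(cvd_meds[i])
        history.append(frozenset(hist))
        medications.append(frozenset(meds))

    ids = genotypes.sample_ids
    phenotypes = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(female, "F", "M"),
            "weight": weight,
            "height": height,
            "smoking": smoking,
            "history": history,
            "medications": medications,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    latent = pd.DataFrame(
        {
            "raw_grs": raw,
            "analysis_group": np.where(in_high_group, "intermediate_high", "low"),
            "bmi_latent": bmi,
            "t2dm_true": t2dm,
            "cvd_true": cvd,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return phenotypes, latent


def generate(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full cohort (genotypes + phenotypes) from one seeded stream."""
    rng = np.random.default_rng(spec.seed)
    genotypes = gen_genotypes(spec.freqs, spec.n, rng, panel=spec.panel)
    phenotypes, latent = gen_phenotypes(spec, genotypes, rng)
    return SyntheticCohort(genotypes, phenotypes, spec, latent)


def emulate_study(seed: int, n: int = STUDY_N) -> SyntheticCohort:
    """A cohort with the default study conditions (n = 4279 analysis-ready
    participants and the descriptive targets listed in the module docstring)."""
    return generate(CohortSpec(n=n, seed=seed))
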