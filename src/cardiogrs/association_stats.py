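"""Contingency-table association statistics and cohort descriptives.

Associations between the merged GRS analysis group (intermediate/high vs
low) and binary outcomes are summarised by the cross-product odds ratio of
the 2x2 table with a Woolf (log-method) 95% CI,

    OR = (a d) / (b c),   CI = exp(ln OR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d)),

the uncorrected Pearson chi-square p-value, and Fisher's exact test where
expected cell counts are small.  The Woolf interval is identical to the Wald
interval of a single-binary-predictor logistic regression, which the test
suite verifies against an independent fit.

Group differences on continuous variables use the Mann-Whitney U test (or
Welch's t when a Shapiro-Wilk check does not reject normality); descriptive
summaries are median +/- IQR or mean +/- SD accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure x outcome table.

    a = exposed & outcome+, b = exposed & outcome-,
    c = unexposed & outcome+, d = unexposed & outcome-.
    """

    a: float
    b: float
    c: float
    d: float
    exposure_label: str = "intermediate_high"
    outcome_label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped_exposure(self) -> "ContingencyTable":
        return ContingencyTable(
            self.c, self.d, self.a, self.b,
            exposure_label=f"not_{self.exposure_label}",
            outcome_label=self.outcome_label,
        )


def table_from_cohort(
    df: pd.DataFrame,
    outcome: str,
    group_col: str = "analysis_group",
    exposed: str = "intermediate_high",
    outcome_label: str | None = None,
) -> ContingencyTable:
    """Build the 2x2 table of a boolean outcome column by analysis group."""
    is_exp = df[group_col] == exposed
    y = df[outcome].astype(bool)
    return ContingencyTable(
        a=int((is_exp & y).sum()),
        b=int((is_exp & ~y).sum()),
        c=int((~is_exp & y).sum()),
        d=int((~is_exp & ~y).sum()),
        exposure_label=exposed,
        outcome_label=outcome_label or outcome,
    )


@dataclass(frozen=True)
class ORResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "woolf_log"
    haldane_corrected: bool = False


def odds_ratio(t: ContingencyTable, z: float = 1.959963984540054) -> ORResult:
    """Cross-product OR with Woolf log-method CI and chi-square p-value.

    Tables containing zero cells get the Haldane-Anscombe +0.5 correction
    (flagged in the result); a double zero in a cross pattern (a=d=0 or
    b=c=0) leaves the OR undefined and raises.
    """
    a, b, c, d = t.cells
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise ValueError("odds ratio undefined: zero cells in a cross pattern")
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_est) - z * se), math.exp(math.log(or_est) + z * se)
    _, p = chi_square_test(t)
    return ORResult(or_est, lo, hi, p, haldane_corrected=corrected)


def chi_square_test(
    t: ContingencyTable, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table (df = 1), uncorrected by default."""
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined for a table with a zero margin")
    res = stats.chi2_contingency(arr, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def expected_counts(t: ContingencyTable) -> np.ndarray:
    arr = t.as_array()
    n = arr.sum()
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables with the observed margins no more probable than the observed one.

    A relative tie guard of 1e-7 treats tables whose probability equals the
    observed one up to float noise as ties (the standard convention).
    """
    a, b, c, d = (int(x) for x in t.cells)
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (n - row1)), min(col1, row1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (two-sided).  Exact enumeration for small tie-free
    samples, tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk normality test; requires 3 <= n <= 5000, non-constant."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DescriptiveRow:
    variable: str
    overall: str
    per_group: dict[str, str] = field(default_factory=dict)
    test: str = ""
    p_value: float = float("nan")
    note: str = ""


def _cont_summary(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"
    q1, q3 = np.percentile(x, [25, 75])
    return f"{np.median(x):.2f} ± {q3 - q1:.2f}"


def _prop_summary(counts: pd.Series, order: list[str]) -> str:
    total = counts.sum()
    parts = [f"{int(counts.get(k, 0))} ({100 * counts.get(k, 0) / total:.1f})"
             for k in order]
    return "/".join(parts)


def _cat_test(sub: pd.DataFrame, var: str, groups: list[str]) -> tuple[str, float, str]:
    tab = pd.crosstab(sub["analysis_group"], sub[var])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return "none", float("nan"), "degenerate: a category is absent in a group"
    arr = tab.to_numpy()
    expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
    if arr.shape == (2, 2) and (expected < 5).any():
        t = ContingencyTable(*arr.ravel())
        return "fisher", fisher_exact(t), ""
    res = stats.chi2_contingency(arr, correction=False)
    return "chi_square", float(res.pvalue), ""


def descriptive_table(df: pd.DataFrame, shapiro_alpha: float = 0.05) -> pd.DataFrame:
    """Cohort characteristics overall and by analysis group, with tests.

    ``df`` must carry age, sex, bmi, bmi_class, bmi_class3, t2dm, cvd,
    smoking, scaled (GRS) and analysis_group columns (the pipeline's merged
    frame).  Continuous rows report median +/- IQR with a Mann-Whitney test
    unless Shapiro-Wilk fails to reject normality (then mean +/- SD, Welch t);
    categorical rows report n (%) with chi-square, or Fisher's exact when an
    expected cell is below 5.
    """
    groups = [g for g in ("low", "intermediate_high") if (df["analysis_group"] == g).any()]
    if len(groups) < 2:
        raise ValueError("descriptive table needs both analysis groups present")
    rows: list[DescriptiveRow] = []

    def add_continuous(var: str, label: str) -> None:
        x = df[var].to_numpy(dtype=float)
        sub = x if len(x) <= 5000 else np.random.default_rng(0).choice(x, 5000, replace=False)
        _, p_norm = shapiro_wilk(sub)
        normal = p_norm >= shapiro_alpha
        xs = [df.loc[df["analysis_group"] == g, var].to_numpy(dtype=float) for g in groups]
        if normal:
            test, p = "t_test", float(stats.ttest_ind(*xs, equal_var=False).pvalue)
        else:
            test = "mann_whitney"
            _, p = mann_whitney(*xs)
        rows.append(
            DescriptiveRow(
                label,
                _cont_summary(x, normal),
                {g: _cont_summary(v, normal) for g, v in zip(groups, xs)},
                test,
                p,
            )
        )

    def add_categorical(var: str, label: str, order: list[str]) -> None:
        work = df.copy()
        if work[var].dtype == bool:
            work[var] = np.where(work[var], "yes", "no")
        test, p, note = _cat_test(work, var, groups)
        rows.append(
            DescriptiveRow(
                label,
                _prop_summary(work[var].value_counts(), order),
                {
                    g: _prop_summary(
                        work.loc[work["analysis_group"] == g, var].value_counts(), order
                    )
                    for g in groups
                },
                test,
                p,
                note,
            )
        )

    add_continuous("age", "Age, years")
    add_categorical("sex", "Sex, M/F (%)", ["M", "F"])
    add_continuous("bmi", "BMI, kg/m2")
    add_categorical(
        "bmi_class", "BMI categories, normal/overweight-obese (%)",
        ["normal", "overweight_obese"],
    )
    add_categorical("t2dm", "T2DM, yes/no (%)", ["yes", "no"])
    add_categorical("cvd", "CVD, yes/no (%)", ["yes", "no"])
    add_categorical("smoking", "Smoking status, yes/no (%)", ["yes", "no"])
    add_continuous("scaled", "Genetic Risk Score (0-100)")

    out = pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "overall": [r.overall for r in rows],
            **{
                f"group_{g}": [r.per_group.get(g, "") for r in rows] for g in groups
            },
            "test": [r.test for r in rows],
            "p_value": [r.p_value for r in rows],
            "note": [r.note for r in rows],
        }
    )
    return out
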