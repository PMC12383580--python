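"""BMI derivation, Tukey outer-fence outlier filtering, and T2DM/CVD status.

Phenotypes come from a self-report questionnaire: weight/height, disease
history flags and free-text medication labels.  Case status is rule-based:

* T2DM+ — positive T2DM history, or use of a glucose-lowering medication
  (insulin, metformin, sulfonylurea).  Individuals whose only qualifying
  evidence is medication and who also carry a GLP-1 receptor agonist or a
  weight-loss drug are set to T2DM-: those prescriptions are commonly issued
  for weight management in people without diabetes, and a positive history
  always wins over the override.
* CVD+ — any of hypertension, coronary artery disease, stroke or
  dyslipidemia in the history, or any cardiovascular medication class
  (antihypertensive, lipid-lowering, antiplatelet/anticoagulant).

BMI quality control removes extreme values outside Tukey's *outer* fences
(Q1 - 3 IQR, Q3 + 3 IQR), computed once on the full input with Tukey-hinge
quartiles (the convention matching boxplot construction for skewed data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# medication classes recognized by the classifiers
T2DM_MED_CLASSES = frozenset({"insulin", "metformin", "sulfonylurea"})
OVERRIDE_CLASS = "glp1_or_weightloss"
CVD_MED_CLASSES = frozenset(
    {"antihypertensive", "lipid_lowering", "antiplatelet_anticoagulant"}
)
CVD_HISTORY_FLAGS = frozenset(
    {"hypertension", "coronary_artery_disease", "stroke", "dyslipidemia"}
)


@dataclass(frozen=True)
class BMIResult:
    bmi: float
    binary_class: str  # normal | overweight_obese
    three_class: str  # normal | overweight | obese


def compute_bmi(weight: float, height: float) -> BMIResult:
    """BMI = weight / height**2 with the standard clinical cut-offs.

    Normal < 25, overweight 25-29.9, obese >= 30 kg/m2; the binary analysis
    class merges overweight and obese.
    """
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be positive")
    bmi = weight / height**2
    if bmi < 25:
        return BMIResult(bmi, "normal", "normal")
    if bmi < 30:
        return BMIResult(bmi, "overweight_obese", "overweight")
    return BMIResult(bmi, "overweight_obese", "obese")


def bmi_binary_class(bmi: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(bmi) >= 25, "overweight_obese", "normal")


def bmi_three_class(bmi: np.ndarray) -> np.ndarray:
    b = np.asarray(bmi)
    return np.select([b < 25, b < 30], ["normal", "overweight"], default="obese")


@dataclass(frozen=True)
class FenceBounds:
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    multiplier: float = 3.0
    quartile_method: str = "hinges"


def tukey_hinges(values: Sequence[float]) -> tuple[float, float]:
    """Tukey's hinges: medians of the lower/upper half, the overall median
    included in both halves when n is odd."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    half = (n + 1) // 2
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def tukey_fences(values: Sequence[float], multiplier: float = 3.0) -> FenceBounds:
    q1, q3 = tukey_hinges(values)
    iqr = q3 - q1
    return FenceBounds(
        q1=q1,
        q3=q3,
        iqr=iqr,
        lower_fence=q1 - multiplier * iqr,
        upper_fence=q3 + multiplier * iqr,
        multiplier=multiplier,
    )


def tukey_outlier_mask(
    values: Sequence[float], multiplier: float = 3.0
) -> tuple[np.ndarray, FenceBounds]:
    """Boolean mask of values *strictly* outside the fences (True = outlier).

    Fences are computed once on the full input (single pass, no re-fencing).
    Requires at least 4 values.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 values to compute Tukey fences")
    b = tukey_fences(x, multiplier)
    return (x < b.lower_fence) | (x > b.upper_fence), b


def tukey_outer_fence_filter(
    values: Sequence[float], multiplier: float = 3.0
) -> tuple[np.ndarray, np.ndarray, FenceBounds]:
    """Split ``values`` into (kept, removed, bounds) by the outer fences."""
    x = np.asarray(values, dtype=float)
    mask, bounds = tukey_outlier_mask(x, multiplier)
    return x[~mask], x[mask], bounds


def load_medication_map(path: str | Path | None = None) -> dict[str, str]:
    """Medication label -> class mapping (TSV ``label<TAB>class``).

    Without a path, the shipped default lexicon is used.
    """
    if path is None:
        src = resources.files("cardiogrs.data") / "medication_classes.tsv"
        text = src.read_text()
    else:
        text = Path(path).read_text()
    med_map: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        label, cls = line.split("\t")
        med_map[label.strip()] = cls.strip()
    return med_map


def _med_classes(medications: Iterable[str], med_map: dict[str, str]) -> set[str]:
    classes = set()
    for label in medications:
        cls = med_map.get(label)
        if cls is None:
            logger.warning("unknown medication label %r classified as 'other'", label)
            cls = "other"
        classes.add(cls)
    return classes


@dataclass(frozen=True)
class OutcomeStatus:
    positive: bool
    provenance: str  # history | medication | override | none


def classify_t2dm(record, med_map: dict[str, str]) -> OutcomeStatus:
    """T2DM status from history and glucose-lowering medication.

    ``record`` needs ``history_flags`` and ``medications`` attributes
    (a :class:`~cardiogrs.panel_io.PhenotypeRecord` or equivalent).
    """
    classes = _med_classes(record.medications, med_map)
    if "t2dm" in record.history_flags:
        return OutcomeStatus(True, "history")
    if classes & T2DM_MED_CLASSES:
        if OVERRIDE_CLASS in classes:
            # medication-only evidence, plus a GLP-1/weight-loss drug:
            # treated as weight management without diabetes
            return OutcomeStatus(False, "override")
        return OutcomeStatus(True, "medication")
    return OutcomeStatus(False, "none")


def classify_cvd(record, med_map: dict[str, str]) -> OutcomeStatus:
    classes = _med_classes(record.medications, med_map)
    if record.history_flags & CVD_HISTORY_FLAGS:
        return OutcomeStatus(True, "history")
    if classes & CVD_MED_CLASSES:
        return OutcomeStatus(True, "medication")
    return OutcomeStatus(False, "none")


class _Row:
    __slots__ = ("history_flags", "medications")

    def __init__(self, history, medications):
        self.history_flags = history
        self.medications = medications


def classify_cohort(
    phenotypes: pd.DataFrame, med_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Vectorised wrapper: derive bmi, BMI classes and both outcome statuses.

    ``phenotypes`` is the frame produced by
    :func:`cardiogrs.panel_io.read_phenotypes`.  Returns a copy with columns
    ``bmi``, ``bmi_class``, ``bmi_class3``, ``t2dm``, ``t2dm_provenance``,
    ``cvd``, ``cvd_provenance`` added.
    """
    if med_map is None:
        med_map = load_medication_map()
    out = phenotypes.copy()
    out["bmi"] = out["weight"] / out["height"] ** 2
    out["bmi_class"] = bmi_binary_class(out["bmi"].to_numpy())
    out["bmi_class3"] = bmi_three_class(out["bmi"].to_numpy())
    t2dm, t2dm_src, cvd, cvd_src = [], [], [], []
    for hist, meds in zip(out["history"], out["medications"]):
        row = _Row(hist, meds)
        st = classify_t2dm(row, med_map)
        t2dm.append(st.positive)
        t2dm_src.append(st.provenance)
        sc = classify_cvd(row, med_map)
        cvd.append(sc.positive)
        cvd_src.append(sc.provenance)
    out["t2dm"] = t2dm
    out["t2dm_provenance"] = t2dm_src
    out["cvd"] = cvd
    out["cvd_provenance"] = cvd_src
    return out
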