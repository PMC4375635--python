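"""Normative limits, classification, lateralisation and diagnostic accuracy.

A hippocampus is abnormal when its measure strictly exceeds the control
mean + 2 SD upper limit (a value exactly at the limit is normal — the
strict inequality is what keeps a borderline control on the normal side).
Limits are fitted on all control hippocampi pooled (left and right
together) with the sample SD (n - 1 denominator).

Diagnostic accuracy is reported for two units of analysis:

* hippocampus — TP/FN over the patients' ipsilateral (ground-truth)
  hippocampi, TN/FP over all control hippocampi;
* subject — a patient is TP when the ipsilateral hippocampus is flagged; a
  control is FP when either hippocampus is flagged.

The headline operating point pairs hippocampus-unit sensitivity with
subject-unit specificity; both units are always available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .roi import HippocampusMeasure
from .cohort import SubjectGroundTruth

__all__ = [
    "NormativeLimits",
    "SubjectClassification",
    "DiagnosticPerformance",
    "BilateralRate",
    "fit_limits",
    "classify",
    "lateralise",
    "evaluate",
    "bilateral_rate",
]


@dataclass(frozen=True)
class NormativeLimits:
    """Control-derived normal limits for one modality (mean + 2 sample SD)."""

    modality: str
    control_mean: float
    control_sd: float
    upper_limit: float
    n_control_hippocampi: int

    def __post_init__(self) -> None:
        expected = self.control_mean + 2.0 * self.control_sd
        if abs(self.upper_limit - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ConfigurationError("upper_limit must equal mean + 2*SD")
        if self.n_control_hippocampi < 2:
            raise InsufficientDataError("need >= 2 control hippocampi")


@dataclass(frozen=True)
class SubjectClassification:
    subject_id: str
    modality: str
    left_abnormal: bool
    right_abnormal: bool

    @property
    def call(self) -> str:
        if self.left_abnormal and self.right_abnormal:
            return "bilateral"
        if self.left_abnormal:
            return "left_hs"
        if self.right_abnormal:
            return "right_hs"
        return "normal"


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion-matrix counts and rates for one modality and unit."""

    modality: str
    unit_of_analysis: str  # "hippocampus" | "subject"
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    def as_dict(self) -> dict:
        return {
            "modality": self.modality,
            "unit_of_analysis": self.unit_of_analysis,
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": round(self.sensitivity, 1),
            "specificity": round(self.specificity, 1),
        }


class BilateralRate(NamedTuple):
    n_contralateral_abnormal: int
    n_patients: int
    percent: float          # raw fraction * 100
    percent_rounded: int    # integer for human-readable reporting


def fit_limits(
    control_measures: Iterable[HippocampusMeasure], modality: str
) -> NormativeLimits:
    """Fit mean + 2 sample SD limits on pooled control hippocampi."""
    values = [m.value for m in control_measures if m.modality == modality]
    if len(values) < 2:
        raise InsufficientDataError(
            f"need >= 2 control {modality} measures, got {len(values)}"
        )
    arr = np.asarray(values, dtype=np.float64)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return NormativeLimits(
        modality=modality,
        control_mean=mean,
        control_sd=sd,
        upper_limit=mean + 2.0 * sd,
        n_control_hippocampi=len(values),
    )


def classify(measure: HippocampusMeasure, limits: NormativeLimits) -> bool:
    """True iff the measure strictly exceeds the normal upper limit."""
    if measure.modality != limits.modality:
        raise ConfigurationError(
            f"modality mismatch: measure {measure.modality!r} vs limits "
            f"{limits.modality!r}"
        )
    return measure.value > limits.upper_limit


def lateralise(
    left: HippocampusMeasure,
    right: HippocampusMeasure,
    limits: NormativeLimits,
) -> SubjectClassification:
    """Per-side classification; both sides abnormal means bilateral."""
    if left is None or right is None:
        raise ConfigurationError("both sides are required for lateralisation")
    if left.subject_id != right.subject_id:
        raise ConfigurationError("left/right measures belong to different subjects")
    return SubjectClassification(
        subject_id=left.subject_id,
        modality=limits.modality,
        left_abnormal=classify(left, limits),
        right_abnormal=classify(right, limits),
    )


def _index_truth(ground_truth: Iterable[SubjectGroundTruth]) -> dict[str, SubjectGroundTruth]:
    return {gt.subject_id: gt for gt in ground_truth}


def evaluate(
    classifications: Iterable[SubjectClassification],
    ground_truth: Iterable[SubjectGroundTruth],
    modality: str,
    unit_of_analysis: str = "hippocampus",
) -> DiagnosticPerformance:
    """Confusion-matrix counts of the threshold classifier.

    Sensitivity is always judged on the patients' ipsilateral hippocampi
    (the ground-truth sclerotic side).  Specificity counts control
    hippocampi individually (``unit_of_analysis='hippocampus'``) or control
    subjects, flagged when either side is abnormal (``'subject'``).
    """
    if unit_of_analysis not in ("hippocampus", "subject"):
        raise ConfigurationError(f"unknown unit_of_analysis {unit_of_analysis!r}")
    truth = _index_truth(ground_truth)
    cls_list = [c for c in classifications if c.modality == modality]
    seen = {c.subject_id for c in cls_list}
    if seen != set(truth):
        raise ConfigurationError(
            "classification and ground-truth subject sets differ: "
            f"{sorted(seen ^ set(truth))[:5]} ..."
        )
    tp = fn = tn = fp = 0
    for c in cls_list:
        gt = truth[c.subject_id]
        if gt.group == "patient":
            ipsi_flag = c.left_abnormal if gt.hs_side == "left" else c.right_abnormal
            if ipsi_flag:
                tp += 1
            else:
                fn += 1
        else:
            if unit_of_analysis == "hippocampus":
                for flag in (c.left_abnormal, c.right_abnormal):
                    if flag:
                        fp += 1
                    else:
                        tn += 1
            else:
                if c.left_abnormal or c.right_abnormal:
                    fp += 1
                else:
                    tn += 1
    return DiagnosticPerformance(
        modality=modality, unit_of_analysis=unit_of_analysis,
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


def bilateral_rate(
    classifications: Iterable[SubjectClassification],
    ground_truth: Iterable[SubjectGroundTruth],
) -> BilateralRate:
    """Fraction of patients whose contralateral hippocampus is flagged."""
    truth = _index_truth(ground_truth)
    n_patients = 0
    n_contra = 0
    for c in classifications:
        gt = truth.get(c.subject_id)
        if gt is None or gt.group != "patient":
            continue
        n_patients += 1
        contra_flag = c.right_abnormal if gt.hs_side == "left" else c.left_abnormal
        if contra_flag:
            n_contra += 1
    if n_patients == 0:
        raise InsufficientDataError("no patient classifications supplied")
    pct = 100.0 * n_contra / n_patients
    return BilateralRate(n_contra, n_patients, pct, int(round(pct)))
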