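"""Diagnostic concordance between organoid calls and clinical labels.

Clinically sensitive patients are the positive class: a sensitive organoid
call in a clinically sensitive patient is a true positive, a resistant call
in a clinically resistant patient a true negative.  Patients adjudicated
not-evaluable — and patients with a call but no clinical adjudication —
are excluded from all denominators and counted in ``excluded``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .cohort import Cohort, NOT_EVALUABLE, RESISTANT, SENSITIVE
from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "ConfusionMatrix",
    "build_confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "compare_indices",
    "ComparisonReport",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp, self.excluded) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp + self.excluded

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
                "excluded": self.excluded}


def build_confusion(calls: Mapping[str, str],
                    adjudications: Mapping[str, str] | Cohort,
                    drug: str | None = None) -> ConfusionMatrix:
    """Tally organoid ``calls`` (patient_id -> sensitive/resistant) against
    adjudicated clinical labels.

    ``adjudications`` is either a patient_id -> label mapping or a
    :class:`Cohort` (then ``drug`` selects the clinical line).  A call with
    no matching adjudication is excluded with a warning.
    """
    if isinstance(adjudications, Cohort):
        if drug is None:
            raise ValidationError("drug required when passing a Cohort")
        labels = adjudications.adjudicated_labels(drug)
    else:
        labels = dict(adjudications)

    tp = fn = tn = fp = excluded = 0
    for pid, call in sorted(calls.items()):
        label = labels.get(pid)
        if label is None:
            warnings.warn(f"call for patient {pid} has no clinical adjudication; excluded")
            excluded += 1
            continue
        if label == NOT_EVALUABLE:
            excluded += 1
        elif label == SENSITIVE:
            tp, fn = (tp + 1, fn) if call == SENSITIVE else (tp, fn + 1)
        elif label == RESISTANT:
            tn, fp = (tn + 1, fp) if call == RESISTANT else (tn, fp + 1)
        else:
            raise ValidationError(f"unknown adjudicated label {label!r}")
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp, excluded=excluded)


def sensitivity(cm: ConfusionMatrix) -> float:
    """True-positive rate over clinically sensitive patients, in percent."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no clinically sensitive patients")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """True-negative rate over clinically resistant patients, in percent."""
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no clinically resistant patients")
    return 100.0 * cm.tn / (cm.tn + cm.fp)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of evaluable patients whose call matches the clinical label."""
    n = cm.tp + cm.fn + cm.tn + cm.fp
    if n == 0:
        raise UndefinedMetricError("accuracy undefined: no evaluable patients")
    return (cm.tp + cm.tn) / n


@dataclass
class ComparisonReport:
    """AUC-only vs CODRP concordance on identical inputs, for one drug."""

    drug: str
    confusion: dict[str, ConfusionMatrix]
    metrics: dict[str, dict[str, float]]
    discordant: dict[str, list[str]]

    @property
    def delta(self) -> dict[str, float]:
        """CODRP minus AUC-only, per metric (only metrics defined in both modes)."""
        out = {}
        for name in set(self.metrics.get("codrp", {})) & set(self.metrics.get("auc", {})):
            out[name] = self.metrics["codrp"][name] - self.metrics["auc"][name]
        return out

    def as_dict(self) -> dict:
        return {
            "drug": self.drug,
            "confusion": {m: cm.as_dict() for m, cm in self.confusion.items()},
            "metrics": self.metrics,
            "delta": self.delta,
            "discordant": self.discordant,
        }


def _metrics(cm: ConfusionMatrix) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, fn in (("sensitivity_pct", sensitivity),
                     ("specificity_pct", specificity),
                     ("accuracy", accuracy)):
        try:
            out[name] = round(fn(cm), 1) if name.endswith("_pct") else round(fn(cm), 4)
        except UndefinedMetricError:
            pass
    return out


def compare_indices(cohort: Cohort, drug: str,
                    calls_by_mode: Mapping[str, Mapping[str, str]] | None = None,
                    ) -> ComparisonReport:
    """Paired AUC-only vs CODRP report against the cohort's clinical labels.

    ``calls_by_mode`` (``{"codrp": {...}, "auc": {...}}``) defaults to the
    cohort's stored screening calls.  Discordant lists name the evaluable
    patients whose call opposes the clinical label, per mode.
    """
    labels = cohort.adjudicated_labels(drug)
    if calls_by_mode is None:
        calls_by_mode = {m: cohort.calls(drug, m) for m in ("codrp", "auc")}

    confusion: dict[str, ConfusionMatrix] = {}
    metrics: dict[str, dict[str, float]] = {}
    discordant: dict[str, list[str]] = {}
    for mode, calls in calls_by_mode.items():
        if not calls:
            continue
        confusion[mode] = build_confusion(calls, labels)
        metrics[mode] = _metrics(confusion[mode])
        discordant[mode] = sorted(
            pid for pid, call in calls.items()
            if labels.get(pid) in (SENSITIVE, RESISTANT) and call != labels[pid]
        )
    return ComparisonReport(drug=drug, confusion=confusion, metrics=metrics,
                            discordant=discordant)
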