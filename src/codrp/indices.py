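"""Cohort scoring: growth rate, Z-scores, AUC index, CODRP index, calls.

The AUC index for a drug is the cohort Z-score of the per-patient AUC:
``(AUC - mean) / SD``.  The CODRP index additionally folds in the
organoid growth rate (a sample property measured on vehicle-control wells,
days 1-3): each patient is placed at ``(Z_growth, Z_AUC)`` and scored by
Euclidean distance from the reference point ``(-4.5, -4.5)`` — the Z-value
below which less than 0.003% of a normal distribution lies, i.e. an
idealized maximally drug-sensitive, non-growing sample.  Distance from the
reference increases with resistance.  The distances are re-Z-scored across
the cohort (per drug, never pooled across drugs) to give the CODRP index,
and a fixed cutoff (default -0.17, inclusive on the sensitive side)
separates sensitive from resistant calls.

All Z-scores use the sample standard deviation (n - 1) by default;
``sd_mode="population"`` is available for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError, ZeroVarianceError

__all__ = [
    "GrowthRecord",
    "IndexConfig",
    "growth_rate",
    "zscore",
    "codrp_distance",
    "codrp_index",
    "classify",
    "score_cohort",
    "derive_cutoff_youden",
    "load_growth",
]

#: relative spread below which a column is treated as constant (its Z-scores
#: collapse to 0 instead of amplifying numerical jitter); applied only to the
#: growth column via ``score_cohort`` — ``zscore`` itself stays strict
DEGENERATE_SD_TOL = 1e-8

GROWTH_COLUMNS = ["patient_id", "mean_area_day1", "mean_area_day3"]


@dataclass(frozen=True)
class GrowthRecord:
    """Mean live-organoid area (consistent units, e.g. um^2) at days 1 and 3."""

    patient_id: str
    mean_area_day1: float
    mean_area_day3: float

    @property
    def growth_rate(self) -> float:
        return growth_rate(self.mean_area_day1, self.mean_area_day3)


@dataclass(frozen=True)
class IndexConfig:
    reference_z: float = -4.5
    cutoff: float = -0.17
    sd_mode: str = "sample"

    def __post_init__(self) -> None:
        if self.reference_z >= 0:
            raise ValidationError("reference_z must be negative")
        if self.sd_mode not in ("sample", "population"):
            raise ValidationError(f"unknown sd_mode {self.sd_mode!r}")


def growth_rate(mean_area_day1: float, mean_area_day3: float) -> float:
    """Relative area increase (day3 - day1) / day1; negative means shrinkage."""
    if mean_area_day1 <= 0:
        raise ValidationError(f"mean_area_day1 must be > 0, got {mean_area_day1}")
    return (mean_area_day3 - mean_area_day1) / mean_area_day1


def _sd(values: np.ndarray, sd_mode: str) -> float:
    return float(np.std(values, ddof=1 if sd_mode == "sample" else 0))


def zscore(values: Sequence[float], label: str = "values",
           sd_mode: str = "sample") -> np.ndarray:
    """(v - mean) / SD per element.  Raises :class:`ZeroVarianceError` if SD = 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError(f"{label}: need >= 2 values to Z-score, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{label}: non-finite value")
    sd = _sd(v, sd_mode)
    if sd == 0:
        raise ZeroVarianceError(label)
    return (v - v.mean()) / sd


def _zscore_or_constant(values: np.ndarray, label: str, sd_mode: str) -> np.ndarray:
    """Z-score with a degenerate-variance floor: a column whose spread is
    numerically indistinguishable from constant gets Z = 0 everywhere."""
    v = np.asarray(values, dtype=float)
    sd = _sd(v, sd_mode)
    if sd <= DEGENERATE_SD_TOL * max(1.0, abs(float(v.mean()))):
        return np.zeros_like(v)
    return zscore(v, label, sd_mode)


def codrp_distance(z_growth: float, z_auc: float, reference_z: float = -4.5):
    """Euclidean distance of ``(Z_growth, Z_AUC)`` from ``(reference_z, reference_z)``."""
    zg = np.asarray(z_growth, dtype=float)
    za = np.asarray(z_auc, dtype=float)
    if not (np.all(np.isfinite(zg)) and np.all(np.isfinite(za))):
        raise ValidationError("codrp_distance: non-finite input")
    out = np.hypot(zg - reference_z, za - reference_z)
    return float(out) if out.ndim == 0 else out


def classify(index_z: float, cutoff: float = -0.17) -> str:
    """``index_z <= cutoff`` -> sensitive, else resistant (tie counts sensitive)."""
    if not math.isfinite(index_z):
        raise ValidationError("classify: non-finite index value")
    return "sensitive" if index_z <= cutoff else "resistant"


def codrp_index(z_growth: Sequence[float], z_auc: Sequence[float],
                config: IndexConfig = IndexConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient CODRP distance and its cohort Z-score, for one drug.

    Returns ``(distances, codrp_z)``.  Zero variance in the distances (e.g.
    two symmetric patients) propagates as :class:`ZeroVarianceError`.
    """
    zg = np.asarray(z_growth, dtype=float)
    za = np.asarray(z_auc, dtype=float)
    if zg.shape != za.shape:
        raise ValidationError("z_growth and z_auc must have equal length")
    if zg.size < 2:
        raise ValidationError("codrp_index needs >= 2 patients")
    d = codrp_distance(zg, za, config.reference_z)
    return d, zscore(d, "codrp_distance", config.sd_mode)


def score_cohort(aucs: Mapping[str, float], growth_rates: Mapping[str, float],
                 config: IndexConfig = IndexConfig(), drug: str = "") -> pd.DataFrame:
    """Full scoring of one drug across a cohort.

    ``aucs`` and ``growth_rates`` map patient_id -> value and must cover the
    same patients.  Returns one row per patient with columns: auc, z_auc,
    growth_rate, z_growth, codrp_distance, codrp_z, call_codrp, call_auc.
    Row order follows sorted patient_id and never affects the values.
    """
    pids = sorted(aucs)
    if sorted(growth_rates) != pids:
        raise ValidationError(
            f"drug {drug!r}: AUC and growth tables cover different patients")
    if len(pids) < 2:
        raise ValidationError(f"drug {drug!r}: need >= 2 patients to score")
    auc = np.array([aucs[p] for p in pids], dtype=float)
    gr = np.array([growth_rates[p] for p in pids], dtype=float)

    z_auc = zscore(auc, f"auc[{drug}]", config.sd_mode)
    z_growth = _zscore_or_constant(gr, f"growth_rate[{drug}]", config.sd_mode)
    dist, cz = codrp_index(z_growth, z_auc, config)

    return pd.DataFrame({
        "patient_id": pids,
        "drug": drug,
        "auc": auc,
        "z_auc": z_auc,
        "growth_rate": gr,
        "z_growth": z_growth,
        "codrp_distance": dist,
        "codrp_z": cz,
        "call_codrp": [classify(z, config.cutoff) for z in cz],
        "call_auc": [classify(z, config.cutoff) for z in z_auc],
    })


def derive_cutoff_youden(index_values: Sequence[float], labels: Sequence[str]) -> float:
    """Optional utility: Youden-J-optimal cutoff of an index against binary
    sensitive/resistant labels.  Provided for exploration; headline results
    always use the fixed configured cutoff.
    """
    from sklearn.metrics import roc_curve

    z = np.asarray(index_values, dtype=float)
    y = np.array([1 if l == "sensitive" else 0 for l in labels])
    if y.min() == y.max():
        raise ValidationError("need both classes to derive a cutoff")
    # sensitive calls are made at low index values, so score by -index
    fpr, tpr, thr = roc_curve(y, -z)
    best = np.argmax(tpr - fpr)
    return float(-thr[best])


def load_growth(path) -> dict[str, float]:
    """Read growth.csv (patient_id, mean_area_day1, mean_area_day3) -> rates."""
    from .errors import SchemaError

    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"growth table missing columns: {missing}")
    out: dict[str, float] = {}
    for row in df.itertuples(index=False):
        rec = GrowthRecord(row.patient_id, float(row.mean_area_day1),
                           float(row.mean_area_day3))
        out[rec.patient_id] = rec.growth_rate
    return out
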