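"""Clinical cohort model: patients, RECIST-labelled drug lines, adjudication.

The packaged fixture mirrors the published 14-patient EGFR-mutant NSCLC
cohort (advanced adenocarcinoma sampled via malignant pleural effusion).
Each patient carries one clinical line per drug *class* — second-generation
EGFR-TKI rows are filed under ``afatinib`` and third-generation rows under
``osimertinib`` — together with the organoid screening calls made at assay
time under the CODRP and AUC-only scoring modes.

Adjudication maps a RECIST 1.1 label (taken at the time the effusion was
sampled) to a binary sensitive/resistant label:

* PR -> sensitive; PD -> resistant;
* SD with a documented tumor-size decrease -> sensitive, with an increase ->
  resistant, otherwise not evaluable;
* NE -> not evaluable (excluded from concordance denominators).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "PatientRecord",
    "ClinicalAdjudication",
    "Cohort",
    "adjudicate",
    "load_cohort",
    "write_cohort",
    "load_packaged_cohort",
]

CLINICAL_COLUMNS = [
    "patient_id", "sex", "age", "smoking", "stage_at_sampling", "mutations",
    "drug", "line", "recist_label", "tumor_change_pct", "notes",
]
SCREENING_COLUMNS = ["patient_id", "drug", "codrp_call", "auc_call"]

RECIST_LABELS = frozenset({"PR", "PD", "SD", "NE"})
SEXES = frozenset({"male", "female"})
SMOKING = frozenset({"current", "ex", "never"})
CALLS = frozenset({"sensitive", "resistant"})

SENSITIVE = "sensitive"
RESISTANT = "resistant"
NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str
    age: int
    smoking: str
    stage_at_sampling: str
    mutations: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"patient {self.patient_id}: age must be > 0")
        if self.sex not in SEXES:
            raise ValidationError(f"patient {self.patient_id}: unknown sex {self.sex!r}")
        if self.smoking not in SMOKING:
            raise ValidationError(f"patient {self.patient_id}: unknown smoking status {self.smoking!r}")
        if not self.mutations:
            raise ValidationError(f"patient {self.patient_id}: mutation list is empty")


@dataclass(frozen=True)
class ClinicalAdjudication:
    patient_id: str
    drug: str
    recist_label: str
    tumor_change_pct: float | None
    adjudicated: str
    rationale: str = ""


def adjudicate(recist_label: str, tumor_change_pct: float | None = None,
               notes: str = "") -> str:
    """Map a RECIST label (at sampling) to sensitive / resistant / not_evaluable.

    Pure function of its inputs; ``notes`` is carried into the rationale only.
    """
    label = str(recist_label).strip().upper()
    if label not in RECIST_LABELS:
        raise ValidationError(f"unknown RECIST label {recist_label!r}")
    if label == "PR":
        return SENSITIVE
    if label == "PD":
        return RESISTANT
    if label == "NE":
        return NOT_EVALUABLE
    # SD: direction of the measured size change decides, if documented
    if tumor_change_pct is None:
        return NOT_EVALUABLE
    if tumor_change_pct < 0:
        return SENSITIVE
    if tumor_change_pct > 0:
        return RESISTANT
    return NOT_EVALUABLE


@dataclass
class Cohort:
    """Patients + per-drug adjudicated clinical lines + optional screening calls."""

    patients: list[PatientRecord]
    adjudications: list[ClinicalAdjudication]
    #: {(drug, mode): {patient_id: call}} with mode in {"codrp", "auc"}
    screening_calls: dict[tuple[str, str], dict[str, str]] = field(default_factory=dict)
    #: verbatim source table, kept for lossless round-tripping
    table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate patient_id in cohort")
        known = set(ids)
        for adj in self.adjudications:
            if adj.patient_id not in known:
                raise ValidationError(
                    f"adjudication for unknown patient {adj.patient_id!r}")

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def drugs(self) -> list[str]:
        return sorted({a.drug for a in self.adjudications})

    def adjudicated_labels(self, drug: str) -> dict[str, str]:
        """patient_id -> sensitive/resistant/not_evaluable for one drug."""
        return {a.patient_id: a.adjudicated for a in self.adjudications if a.drug == drug}

    def calls(self, drug: str, mode: str = "codrp") -> dict[str, str]:
        """Stored organoid screening calls for one drug and scoring mode."""
        return dict(self.screening_calls.get((drug, mode), {}))


def _parse_change(raw: str) -> float | None:
    raw = raw.strip()
    if not raw:
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise ValidationError(f"bad tumor_change_pct {raw!r}") from exc


def load_cohort(clinical_csv, screening_csv=None) -> Cohort:
    """Read and validate a clinical table (and optional screening-call table).

    The table has one row per patient per drug line; patient attributes must
    be identical across a patient's rows.  Malformed rows are reported with
    their 1-based data row number.
    """
    df = pd.read_csv(clinical_csv, dtype=str, keep_default_na=False)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing columns: {missing}")

    patients: dict[str, PatientRecord] = {}
    adjudications: list[ClinicalAdjudication] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pid = str(row.patient_id).strip()
            rec = PatientRecord(
                patient_id=pid,
                sex=row.sex.strip(),
                age=int(row.age),
                smoking=row.smoking.strip(),
                stage_at_sampling=row.stage_at_sampling.strip(),
                mutations=tuple(m.strip() for m in row.mutations.split(";") if m.strip()),
            )
            if pid in patients and patients[pid] != rec:
                raise ValidationError(f"inconsistent attributes for patient {pid}")
            patients.setdefault(pid, rec)
            key = (pid, row.drug.strip())
            if key in seen:
                raise ValidationError(f"duplicate adjudication for {key}")
            seen.add(key)
            change = _parse_change(row.tumor_change_pct)
            adjudications.append(ClinicalAdjudication(
                patient_id=pid,
                drug=row.drug.strip(),
                recist_label=row.recist_label.strip().upper(),
                tumor_change_pct=change,
                adjudicated=adjudicate(row.recist_label, change, row.notes),
                rationale=row.notes,
            ))
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"clinical row {i}: {exc}") from exc

    calls: dict[tuple[str, str], dict[str, str]] = {}
    if screening_csv is not None:
        sdf = pd.read_csv(screening_csv, dtype=str, keep_default_na=False)
        missing = [c for c in SCREENING_COLUMNS if c not in sdf.columns]
        if missing:
            raise SchemaError(f"screening table missing columns: {missing}")
        for i, row in enumerate(sdf.itertuples(index=False), start=1):
            for mode, raw in (("codrp", row.codrp_call), ("auc", row.auc_call)):
                token = raw.strip().lower().replace("resistance", "resistant")
                if not token:
                    continue
                if token not in CALLS:
                    raise ValidationError(f"screening row {i}: unknown call {raw!r}")
                calls.setdefault((row.drug.strip(), mode), {})[row.patient_id.strip()] = token

    return Cohort(list(patients.values()), adjudications, calls, table=df)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the clinical table back to CSV, lossless for loaded cohorts."""
    if cohort.table is not None:
        cohort.table.to_csv(path, index=False)
        return
    by_id = {p.patient_id: p for p in cohort.patients}
    rows = []
    for a in cohort.adjudications:
        p = by_id[a.patient_id]
        rows.append({
            "patient_id": p.patient_id, "sex": p.sex, "age": p.age,
            "smoking": p.smoking, "stage_at_sampling": p.stage_at_sampling,
            "mutations": ";".join(p.mutations), "drug": a.drug, "line": "",
            "recist_label": a.recist_label,
            "tumor_change_pct": "" if a.tumor_change_pct is None else a.tumor_change_pct,
            "notes": a.rationale,
        })
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def load_packaged_cohort() -> Cohort:
    """The bundled 14-patient EGFR-TKI cohort with its screening calls."""
    data = importlib.resources.files("codrp.data")
    with importlib.resources.as_file(data / "clinical.csv") as clin, \
            importlib.resources.as_file(data / "screening.csv") as scr:
        return load_cohort(clin, scr)
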