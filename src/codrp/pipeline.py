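"""End-to-end orchestration: plate + growth + clinical -> indices + concordance.

`run_pipeline` is the function behind the ``codrp run`` CLI subcommand; it
reads the three input tables, scores every drug present on the plate, writes
``indices.csv`` (one row per patient x drug) and ``concordance.json`` (per
drug and scoring mode: confusion counts, metrics, discordant patients), and
stamps both with a hash of the effective configuration so runs are
attributable and byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, load_cohort
from .concordance import compare_indices
from .drc import PLATE_COLUMNS, DoseResponseProfile, profile_auc
from .errors import SchemaError
from .indices import IndexConfig, load_growth, score_cohort

__all__ = ["profiles_from_frame", "run_pipeline", "config_hash"]


def profiles_from_frame(df: pd.DataFrame) -> dict[tuple[str, str], DoseResponseProfile]:
    """Group a long-format plate table into per-(patient, drug) profiles."""
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"plate table missing columns: {missing}")
    df = df.astype({"patient_id": str, "drug": str})
    profiles: dict[tuple[str, str], DoseResponseProfile] = {}
    for (pid, drug), grp in df.groupby(["patient_id", "drug"], sort=True):
        dmso = grp.loc[grp["conc_uM"] == 0, "readout"].to_numpy(float)
        dosed = grp[grp["conc_uM"] > 0]
        conc = np.sort(dosed["conc_uM"].unique())[::-1]
        reps = [dosed.loc[dosed["conc_uM"] == c, "readout"].to_numpy(float) for c in conc]
        profiles[(pid, drug)] = DoseResponseProfile(pid, drug, conc, reps, dmso)
    return profiles


def config_hash(config: IndexConfig, extra: dict | None = None) -> str:
    payload = dataclasses.asdict(config)
    if extra:
        payload.update(extra)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(plate_csv, growth_csv, clinical_csv, out_dir,
                 index_config: IndexConfig = IndexConfig(),
                 screening_csv=None, mode: str = "both") -> dict:
    """Score every drug on the plate and compare calls with clinical labels.

    ``mode`` selects which call columns feed the concordance report:
    ``codrp``, ``auc_only`` or ``both``.  If ``plate_csv`` and ``growth_csv``
    are both omitted, calls are taken from the stored screening-call table
    instead of being recomputed (the archival-cohort path; ``screening_csv``
    is then required and only ``concordance.json`` is written).  Returns the
    concordance report as a dict, also written to ``out_dir``.
    """
    if mode not in ("codrp", "auc_only", "both"):
        raise SchemaError(f"unknown mode {mode!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    modes = {"codrp": ["codrp"], "auc_only": ["auc"], "both": ["codrp", "auc"]}[mode]
    cohort = load_cohort(clinical_csv, screening_csv)
    stamp = config_hash(index_config, {"mode": mode})
    reports = {}

    if plate_csv is None and growth_csv is None:
        if screening_csv is None:
            raise SchemaError(
                "without plate/growth inputs a screening-call table is required")
        for drug in cohort.drugs():
            calls_by_mode = {m: cohort.calls(drug, m) for m in modes
                             if cohort.calls(drug, m)}
            if calls_by_mode and cohort.adjudicated_labels(drug):
                reports[drug] = compare_indices(cohort, drug, calls_by_mode).as_dict()
    elif plate_csv is None or growth_csv is None:
        missing = "plate" if plate_csv is None else "growth"
        raise SchemaError(f"missing required input: {missing} table "
                          "(plate and growth must be provided together)")
    else:
        plate = pd.read_csv(plate_csv)
        profiles = profiles_from_frame(plate)
        growth = load_growth(growth_csv)
        frames = []
        for drug in sorted({drug for (_, drug) in profiles}):
            aucs = {pid: profile_auc(prof).auc
                    for (pid, d), prof in profiles.items() if d == drug}
            scored = score_cohort(aucs, {p: growth[p] for p in aucs},
                                  index_config, drug=drug)
            frames.append(scored)
            calls_by_mode = {m: dict(zip(scored["patient_id"], scored[f"call_{m}"]))
                             for m in modes}
            if cohort.adjudicated_labels(drug):
                reports[drug] = compare_indices(cohort, drug, calls_by_mode).as_dict()
        indices = pd.concat(frames, ignore_index=True)
        indices.insert(0, "config_hash", stamp)
        indices.to_csv(out / "indices.csv", index=False)

    report = {"config_hash": stamp, "mode": mode, "drugs": reports}
    (out / "concordance.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
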