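"""Cohort CSV serialization: one row per patient, 0/1 feature columns.

Schema: mandatory ``id`` and ``group`` columns; optional ``polyA``,
``index_disease``, ``sex``, age columns and one 0/1 column per
subphenotype flag; one 0/1 column per vocabulary feature.  Unknown
columns are preserved on read with a warning; a vocabulary feature
column that is absent is treated as absent-for-everyone (0).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import pandas as pd

from .cohort import CohortSpec, CohortTable, default_spec
from .records import (
    VOCABULARY,
    Group,
    IndexDisease,
    PatientRecord,
    Sex,
    Subphenotype,
)

_SUBPHENOTYPE_COLS = tuple(s.value for s in Subphenotype)
_META_COLS = (
    "id",
    "group",
    "polyA",
    "index_disease",
    "sex",
    "age_years",
    "age_onset_years",
    "age_dx_years",
) + _SUBPHENOTYPE_COLS


def cohort_to_dataframe(cohort: CohortTable) -> pd.DataFrame:
    rows = []
    for r in cohort.records:
        row: dict = {
            "id": r.id,
            "group": r.group.value,
            "polyA": r.polyA,
            "index_disease": r.index_disease.value if r.index_disease else "",
            "sex": r.sex.value if r.sex else "",
            "age_years": r.age_years,
            "age_onset_years": r.age_onset_years,
            "age_dx_years": r.age_dx_years,
        }
        for s in Subphenotype:
            row[s.value] = int(s in r.subphenotypes)
        for f in VOCABULARY:
            row[f] = r.feature(f)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(cohort: CohortTable, path: Union[str, Path]) -> None:
    cohort_to_dataframe(cohort).to_csv(path, index=False)


def _parse_binary(value, column: str, row: int) -> int:
    try:
        iv = int(value)
    except (TypeError, ValueError):
        iv = -1
    if iv not in (0, 1):
        raise ValueError(f"row {row}: column {column!r} must be 0/1, got {value!r}")
    return iv


def read_cohort_csv(path: Union[str, Path], spec: CohortSpec | None = None) -> CohortTable:
    """Load a cohort CSV.  ``spec`` is attached as provenance when given
    (a placeholder spec with matching group sizes is synthesized
    otherwise, purely so the container is self-describing)."""
    df = pd.read_csv(path)
    for col in ("id", "group"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r}")
    feature_cols = [c for c in df.columns if c in VOCABULARY]
    unknown = [c for c in df.columns if c not in _META_COLS and c not in VOCABULARY]
    if unknown:
        warnings.warn(f"preserving unknown columns {unknown}", stacklevel=2)
    records = []
    for i, row in df.iterrows():
        group = Group(row["group"])
        subs = frozenset(
            Subphenotype(s)
            for s in _SUBPHENOTYPE_COLS
            if s in df.columns and _parse_binary(row[s], s, i)
        )
        idx = row.get("index_disease")
        records.append(
            PatientRecord(
                id=str(row["id"]),
                group=group,
                features={c: _parse_binary(row[c], c, i) for c in feature_cols},
                polyA=_parse_binary(row["polyA"], "polyA", i) if "polyA" in df.columns else 0,
                index_disease=IndexDisease(idx) if isinstance(idx, str) and idx else None,
                subphenotypes=subs,
                age_years=float(row["age_years"]) if "age_years" in df.columns and pd.notna(row["age_years"]) else None,
                age_onset_years=float(row["age_onset_years"]) if "age_onset_years" in df.columns and pd.notna(row["age_onset_years"]) else None,
                age_dx_years=float(row["age_dx_years"]) if "age_dx_years" in df.columns and pd.notna(row["age_dx_years"]) else None,
                sex=Sex(row["sex"]) if "sex" in df.columns and isinstance(row["sex"], str) and row["sex"] else None,
            )
        )
    n_case = sum(r.group is Group.case for r in records)
    n_control = len(records) - n_case
    if spec is None:
        base = default_spec()
        spec = base.model_copy(
            update={
                "n_case": max(n_case, 1),
                "n_control": max(n_control, 1),
                "control_disease_mix": {"RA": 1.0},
            }
        )
    return CohortTable(records=records, spec_used=spec, seed_used=spec.seed)
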