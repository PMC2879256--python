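"""Cohort CSV reading/writing and JSON helpers for the CLI.

CSV dialect: comma-separated, UTF-8, header row required, "." decimal.
Sex is encoded "M"/"F" and race "AA"/"NAA" (case-insensitive on read,
canonical on write).
"""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd

from .cohort import CohortRecord
from .errors import BodycompError, CohortCsvError, ValidationError
from .models import RaceGroup, SexCategory, SubjectCovariates
from .solver import FollowUpRecord

COHORT_COLUMNS = ("id", "sex", "race", "age_y", "height_cm", "fm_kg",
                  "ffm_kg")
FOLLOWUP_COLUMNS = ("id", "sex", "race", "age_y", "height_cm",
                    "fm_baseline_kg", "ffm_baseline_kg", "fm_final_kg",
                    "ffm_final_kg")

JSON_SCHEMA_VERSION = 1


def _read_table(path, required_columns):
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{','.join(required_columns)}")
    return df


def read_cohort_csv(path) -> list[CohortRecord]:
    """Read and validate a cross-sectional cohort CSV.

    Row-level failures are collected and raised together as a
    :class:`CohortCsvError` whose message lists line number, record id and
    the offending field.
    """
    df = _read_table(path, COHORT_COLUMNS)
    records, errors = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            records.append(CohortRecord(
                id=str(row.id),
                sex=SexCategory.parse(row.sex),
                race=RaceGroup.parse(row.race),
                age_y=float(row.age_y),
                height_cm=float(row.height_cm),
                fm_kg=float(row.fm_kg),
                ffm_kg=float(row.ffm_kg)))
        except (BodycompError, TypeError) as exc:
            errors.append((line, str(row.id), str(exc)))
    if errors:
        detail = "; ".join(f"line {ln} (id={rid}): {msg}"
                           for ln, rid, msg in errors)
        raise CohortCsvError(f"{path}: {len(errors)} invalid row(s): "
                             f"{detail}", row_errors=errors)
    return records


def write_cohort_csv(records: Sequence[CohortRecord], path) -> None:
    # repr gives the shortest exact float round-trip, which pandas'
    # float_format cannot guarantee
    lines = [",".join(COHORT_COLUMNS)]
    for r in records:
        lines.append(",".join((r.id, r.sex.value, r.race.value,
                               repr(r.age_y), repr(r.height_cm),
                               repr(r.fm_kg), repr(r.ffm_kg))))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_followup_csv(path) -> list[FollowUpRecord]:
    """Read a follow-up cohort (measured baseline and final composition)."""
    df = _read_table(path, FOLLOWUP_COLUMNS)
    records, errors = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        try:
            cov = SubjectCovariates(float(row.age_y), float(row.height_cm),
                                    SexCategory.parse(row.sex),
                                    RaceGroup.parse(row.race))
            records.append(FollowUpRecord(
                id=str(row.id), cov=cov,
                fm_baseline_kg=float(row.fm_baseline_kg),
                ffm_baseline_kg=float(row.ffm_baseline_kg),
                fm_final_kg=float(row.fm_final_kg),
                ffm_final_kg=float(row.ffm_final_kg)))
        except (BodycompError, TypeError) as exc:
            errors.append((line, str(row.id), str(exc)))
    if errors:
        detail = "; ".join(f"line {ln} (id={rid}): {msg}"
                           for ln, rid, msg in errors)
        raise CohortCsvError(f"{path}: {len(errors)} invalid row(s): "
                             f"{detail}", row_errors=errors)
    return records


def to_stable_json(payload: dict) -> str:
    """Schema-stable JSON: versioned, keys sorted."""
    return json.dumps({"schema_version": JSON_SCHEMA_VERSION, **payload},
                      sort_keys=True, indent=2)
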