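"""Cohort CSV reading and writing.

The on-disk cohort format is long: one row per (subject, rater, session,
tooth) observation, comma-separated, UTF-8, '.' decimal.  Long format means
partial dentitions need no sentinel values — teeth simply absent from a
subject's rows are treated as unassessable downstream.

Chronological age is accepted either directly (``ca_years``) or as
``birth_date``/``exam_date`` ISO dates, converted via (exam - birth)/365.25.
"""

from __future__ import annotations

import logging
from datetime import date
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import (
    ApexRecord,
    ApexStatus,
    CohortRecord,
    Sex,
    Stage,
    StageRecord,
    parse_fdi,
)

logger = logging.getLogger(__name__)

__all__ = ["read_cohort", "write_cohort", "write_results", "read_results"]

#: Decimal places preserved by a results round-trip.
RESULT_PRECISION = 6

_REQUIRED = {"subject_id", "sex", "tooth_fdi", "apex_status"}
_ACCEPTED = _REQUIRED | {
    "ca_years",
    "birth_date",
    "exam_date",
    "rater_id",
    "session_id",
    "root_fraction",
    "demirjian_stage",
}

DAYS_PER_YEAR = 365.25


def _decimal_age(row: pd.Series, line: int) -> float:
    if "ca_years" in row.index and not pd.isna(row["ca_years"]):
        return float(row["ca_years"])
    if {"birth_date", "exam_date"} <= set(row.index):
        born = date.fromisoformat(str(row["birth_date"]))
        exam = date.fromisoformat(str(row["exam_date"]))
        return (exam - born).days / DAYS_PER_YEAR
    raise ValueError(f"line {line}: no ca_years and no birth_date/exam_date")


def read_cohort(
    path,
    *,
    plausible_age: tuple[float, float] = (3.0, 25.0),
) -> list[CohortRecord]:
    """Read a long-format cohort CSV into one record per (subject, rater,
    session).

    Errors on unknown columns (listing the accepted schema), on duplicate
    tooth rows within a key group, and on an empty file.  A chronological
    age outside ``plausible_age`` logs a warning but loads.  Third molars
    load (and are warned about); the estimators never consume them.
    """
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"cohort file {path} is empty") from None
    if frame.empty:
        raise ValueError(f"cohort file {path} has no data rows")
    unknown = set(frame.columns) - _ACCEPTED
    if unknown:
        raise ValueError(
            f"unknown column(s) {sorted(unknown)}; accepted schema: {sorted(_ACCEPTED)}"
        )
    missing = _REQUIRED - set(frame.columns)
    if missing:
        raise ValueError(f"cohort file missing required column(s) {sorted(missing)}")
    frame["__line"] = frame.index + 2  # header is line 1
    for col in ("rater_id", "session_id"):
        if col not in frame.columns:
            frame[col] = "R1" if col == "rater_id" else "S1"
        frame[col] = frame[col].fillna("R1" if col == "rater_id" else "S1")

    records: dict[tuple[str, str, str], CohortRecord] = {}
    for key, grp in frame.groupby(["subject_id", "rater_id", "session_id"], sort=True):
        first = grp.iloc[0]
        line0 = int(first["__line"])
        ca = _decimal_age(first, line0)
        if not plausible_age[0] <= ca <= plausible_age[1]:
            logger.warning(
                "subject %s: chronological age %.2f outside plausibility window %s",
                key[0],
                ca,
                plausible_age,
            )
        rec = CohortRecord(
            subject_id=str(key[0]),
            sex=Sex(str(first["sex"]).strip()),
            chronological_age=ca,
            rater_id=str(key[1]),
            session_id=str(key[2]),
        )
        for _, row in grp.iterrows():
            line = int(row["__line"])
            tooth = parse_fdi(row["tooth_fdi"])
            if tooth in rec.apex_records:
                raise ValueError(
                    f"line {line}: duplicate row for subject/rater/session "
                    f"{key} tooth {tooth}"
                )
            if tooth.is_third_molar:
                logger.warning(
                    "line %d: third molar %s recorded; it will not inform estimation",
                    line,
                    tooth,
                )
            frac = row.get("root_fraction")
            frac = None if pd.isna(frac) else float(frac)
            try:
                rec.apex_records[tooth] = ApexRecord(
                    tooth, ApexStatus(str(row["apex_status"]).strip()), frac
                )
            except ValueError as exc:
                raise ValueError(f"line {line}: {exc}") from None
            stage = row.get("demirjian_stage")
            if not pd.isna(stage) and str(stage).strip():
                rec.stage_records[tooth] = StageRecord(tooth, Stage(str(stage).strip()))
        records[rec.key] = rec
    return list(records.values())


def write_cohort(records: Iterable[CohortRecord], path) -> None:
    """Write records back to the long CSV schema (inverse of read_cohort)."""
    rows = []
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        if rec.key in seen:
            raise ValueError(f"duplicate (subject, rater, session) key {rec.key}")
        seen.add(rec.key)
        for tooth in sorted(rec.apex_records):
            apex = rec.apex_records[tooth]
            stage = rec.stage_records.get(tooth)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "sex": rec.sex.value,
                    "ca_years": round(rec.chronological_age, RESULT_PRECISION),
                    "rater_id": rec.rater_id,
                    "session_id": rec.session_id,
                    "tooth_fdi": tooth.fdi,
                    "apex_status": apex.apex_status.value,
                    "root_fraction": (
                        round(apex.root_fraction, RESULT_PRECISION)
                        if apex.root_fraction is not None
                        else ""
                    ),
                    "demirjian_stage": stage.stage.value if stage else "",
                }
            )
    if not rows:
        raise ValueError("no records to write")
    pd.DataFrame(rows).to_csv(path, index=False)


_RESULT_COLUMNS = [
    "subject_id",
    "sex",
    "ca_years",
    "rater_id",
    "session_id",
    "method",
    "da_point",
    "da_low",
    "da_high",
    "flags",
]


def write_results(estimates: pd.DataFrame, path) -> None:
    """Write a per-subject estimates table; numeric columns are rounded to
    ``RESULT_PRECISION`` decimals so a re-read reproduces values exactly."""
    if estimates is None or len(estimates) == 0:
        raise ValueError("empty estimate table")
    out = estimates.copy()
    missing = set(_RESULT_COLUMNS) - set(out.columns)
    if missing:
        raise ValueError(f"estimates table missing columns {sorted(missing)}")
    for col in ("ca_years", "da_point", "da_low", "da_high"):
        out[col] = np.round(out[col].astype(float), RESULT_PRECISION)
    out[_RESULT_COLUMNS].to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"subject_id": str, "flags": str})
    frame["flags"] = frame["flags"].fillna("")
    return frame
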