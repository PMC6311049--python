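"""Cohort tables: reading/writing delimited text, index-event selection,
and exclusion rules.

The cohort file is a CSV with one row per patient carrying the as-stored
demographics (dob, gender, race), the same-day serum creatinine, and the
automated eGFR recorded by the laboratory system at measurement time.

For users mapping real laboratory extracts: serum creatinine is typically
identified by LOINC codes 35203-1, 77140-2, 21232-4, 2160-0, 38483-4,
59826-8, 14682-9. These are documentation metadata only; no terminology
service is consulted.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Tuple, Union

import pandas as pd

from .egfr import Gender, PatientSnapshot, RaceDetail

__all__ = [
    "SCR_LOINC_CODES",
    "COHORT_COLUMNS",
    "LabRecord",
    "CohortRow",
    "CohortSchemaError",
    "CohortValueError",
    "select_index_pairs",
    "apply_exclusions",
    "read_cohort",
    "write_cohort",
]

SCR_LOINC_CODES = (
    "35203-1", "77140-2", "21232-4", "2160-0", "38483-4", "59826-8", "14682-9",
)

COHORT_COLUMNS = (
    "patient_id", "dob", "gender", "race", "scr", "automated_egfr", "lab_date",
)


@dataclass(frozen=True)
class LabRecord:
    """A dated laboratory result: an automated eGFR or a serum creatinine.

    ``panel_member`` is meaningful only for creatinine records and flags an
    Scr drawn as part of a comprehensive metabolic panel rather than as a
    standalone test.
    """

    patient_id: str
    lab_date: _dt.date
    kind: str  # "automated_egfr" | "scr"
    value: float
    panel_member: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.kind not in ("automated_egfr", "scr"):
            raise ValueError(f"unknown lab kind {self.kind!r}")
        if self.value <= 0:
            raise ValueError("lab value must be positive")
        if self.kind == "automated_egfr" and self.panel_member is not None:
            raise ValueError("panel_member applies only to scr records")


@dataclass(frozen=True)
class CohortRow:
    """As-stored demographics plus the paired automated eGFR and Scr."""

    snapshot: PatientSnapshot
    automated_egfr: float

    @property
    def patient_id(self) -> str:
        return self.snapshot.patient_id


class CohortSchemaError(ValueError):
    """Input file is missing required columns."""


class CohortValueError(ValueError):
    """A row holds an unparseable value; carries the 1-based data line number."""


def select_index_pairs(
    labs: Iterable[LabRecord],
    window: Tuple[_dt.date, _dt.date],
) -> Tuple[list, dict]:
    """Pick each patient's first in-window automated eGFR and its same-day Scr.

    Returns ``(pairs, tally)`` where pairs is a list of
    ``(patient_id, egfr_record, scr_record)`` — at most one per patient —
    and tally counts patients dropped for having no same-day Scr
    (``no_same_day_scr``) or only a panel-member Scr (``panel_scr``).

    The earliest in-window eGFR per patient wins, ties broken by input
    order. Among same-day Scr records a standalone (non-panel) one is
    preferred; among several standalone values the first by record order.
    """
    start, end = window
    if start > end:
        raise ValueError("window start after end")
    labs = list(labs)
    first_egfr: dict = {}
    order: dict = {}
    for i, rec in enumerate(labs):
        if rec.kind != "automated_egfr" or not (start <= rec.lab_date <= end):
            continue
        prev = first_egfr.get(rec.patient_id)
        if prev is None or rec.lab_date < prev.lab_date:
            first_egfr[rec.patient_id] = rec
            order.setdefault(rec.patient_id, i)
    pairs = []
    tally = {"no_same_day_scr": 0, "panel_scr": 0}
    for pid in sorted(first_egfr, key=lambda p: order[p]):
        egfr_rec = first_egfr[pid]
        same_day = [
            r for r in labs
            if r.kind == "scr" and r.patient_id == pid and r.lab_date == egfr_rec.lab_date
        ]
        if not same_day:
            tally["no_same_day_scr"] += 1
            continue
        standalone = [r for r in same_day if not r.panel_member]
        if not standalone:
            tally["panel_scr"] += 1
            continue
        pairs.append((pid, egfr_rec, standalone[0]))
    return pairs, tally


def apply_exclusions(df: pd.DataFrame) -> Tuple[pd.DataFrame, dict]:
    """Drop rows with missing race, DOB, or gender; tally reasons.

    A row missing several fields is tallied once, under the first reason in
    the order race, dob, gender. Conservation holds:
    ``len(retained) + sum(tally.values()) == len(df)``.
    """
    tally = {"missing_race": 0, "missing_dob": 0, "missing_gender": 0}
    reasons = pd.Series("", index=df.index)
    for col, reason in (("race", "missing_race"), ("dob", "missing_dob"),
                        ("gender", "missing_gender")):
        missing = df[col].isna() | (df[col].astype(str).str.strip() == "")
        newly = missing & (reasons == "")
        reasons[newly] = reason
        tally[reason] = int(newly.sum())
    retained = df[reasons == ""].copy()
    return retained, tally


def _parse_date(s: str) -> _dt.date:
    return _dt.date.fromisoformat(str(s))


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort CSV, validating schema and per-row values.

    Returns a DataFrame with ISO dates parsed to ``datetime.date`` and
    numeric columns as floats. Raises :class:`CohortSchemaError` naming any
    missing columns, or :class:`CohortValueError` citing the first offending
    data line (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required columns: {', '.join(missing)}")
    out = df.copy()
    for col, conv in (("scr", float), ("automated_egfr", float),
                      ("dob", _parse_date), ("lab_date", _parse_date)):
        parsed = []
        for i, raw in enumerate(df[col]):
            if raw == "" and col == "dob":
                parsed.append(None)  # missing DOB handled by apply_exclusions
                continue
            try:
                parsed.append(conv(raw))
            except (ValueError, TypeError):
                raise CohortValueError(
                    f"unparseable value {raw!r} in column {col!r} at line {i + 1}"
                ) from None
        out[col] = parsed
    return out


def write_cohort(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort table as CSV with ISO-8601 dates; round-trips read_cohort."""
    out = df.copy()
    for col in ("dob", "lab_date"):
        out[col] = out[col].map(lambda d: d.isoformat() if d is not None else "")
    out.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def rows_from_frame(df: pd.DataFrame) -> list:
    """Materialise :class:`CohortRow` objects from a validated cohort frame."""
    rows = []
    for rec in df.itertuples(index=False):
        snap = PatientSnapshot(
            patient_id=str(rec.patient_id),
            dob=rec.dob,
            gender=Gender(rec.gender),
            race_detail=RaceDetail(rec.race),
            scr=float(rec.scr),
            lab_date=rec.lab_date,
        )
        rows.append(CohortRow(snapshot=snap, automated_egfr=float(rec.automated_egfr)))
    return rows
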