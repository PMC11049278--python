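"""Core domain model for statutory-claims tables.

German statutory health insurance (GKV) claims arrive as a set of
delimited tables: patients, insurance coverage periods, diagnoses
(ICD-10-GM; dated when inpatient, calendar-quarter-resolved when
outpatient), prescription fills (ATC), and procedures (OPS).  This module
provides the validated in-memory bundle for those tables, calendar-quarter
arithmetic, per-patient observation windows, and insurance-coverage
fractions — the primitives every downstream stage (cohort selection,
phenotyping, matching, survival) builds on.

Conventions
-----------
* All dates are ISO-8601 in files and ``datetime.date`` in memory; all
  intervals are closed.
* Outpatient diagnoses carry quarter resolution only; whenever a calendar
  date is needed for an outpatient event, the quarter midpoint (quarter
  start + 45 days by default) is used.
* Day counting for coverage is inclusive on both ends: an insurance period
  is a whole-day membership.
"""

from __future__ import annotations

import dataclasses
import re
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "STUDY_START",
    "STUDY_END",
    "QUARTER_MIDPOINT_OFFSET_DAYS",
    "ClaimsError",
    "SchemaError",
    "Quarter",
    "ObservationWindow",
    "ClaimsBundle",
    "quarter_of",
    "quarter_midpoint",
    "observation_window",
    "merge_periods",
    "insurance_coverage_fraction",
    "diagnosis_dates",
    "load_claims_bundle",
    "write_claims_bundle",
]

#: Study era: claims were extracted for 2010-2020 inclusive.
STUDY_START = date(2010, 1, 1)
STUDY_END = date(2020, 12, 31)

#: Day offset from the first day of a quarter to its conventional
#: "midpoint" (quarters span 90-92 days, so day 45 sits near the center).
QUARTER_MIDPOINT_OFFSET_DAYS = 45


class ClaimsError(ValueError):
    """Domain-level validation failure."""


class SchemaError(ClaimsError):
    """A claims table violates its schema.

    Carries the table name, the offending row label (or None for
    table-level problems) and the field, so callers can locate the record.
    """

    def __init__(self, table: str, row, field: str, message: str):
        self.table = table
        self.row = row
        self.field = field
        super().__init__(f"{table}[row={row}].{field}: {message}")


# ---------------------------------------------------------------------------
# Calendar quarters
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True, order=True)
class Quarter:
    """A calendar quarter, totally ordered by (year, index)."""

    year: int
    index: int

    def __post_init__(self):
        if not 1 <= self.index <= 4:
            raise ClaimsError(f"quarter index must be 1..4, got {self.index}")

    @property
    def first_day(self) -> date:
        return date(self.year, 3 * self.index - 2, 1)

    def midpoint(self, offset_days: int = QUARTER_MIDPOINT_OFFSET_DAYS) -> date:
        return self.first_day + timedelta(days=offset_days)

    def successor(self) -> "Quarter":
        if self.index == 4:
            return Quarter(self.year + 1, 1)
        return Quarter(self.year, self.index + 1)

    def predecessor(self) -> "Quarter":
        if self.index == 1:
            return Quarter(self.year - 1, 4)
        return Quarter(self.year, self.index - 1)

    def __str__(self) -> str:
        return f"{self.year}Q{self.index}"


def quarter_of(d: date) -> Quarter:
    """Calendar quarter containing date ``d``."""
    return Quarter(d.year, (d.month + 2) // 3)


def quarter_midpoint(
    q: Quarter, offset_days: int = QUARTER_MIDPOINT_OFFSET_DAYS
) -> date:
    """Conventional date for a quarter-resolved event (start + 45 days)."""
    return q.midpoint(offset_days)


# ---------------------------------------------------------------------------
# Observation windows and coverage
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ObservationWindow:
    """Closed per-patient observation interval within the study era."""

    start: date
    end: date

    def __post_init__(self):
        if self.start >= self.end:
            raise ClaimsError(
                f"observation window start {self.start} not before end {self.end}"
            )

    @property
    def days(self) -> int:
        """Inclusive day count of the window."""
        return (self.end - self.start).days + 1


def observation_window(death_date: date | None = None) -> ObservationWindow:
    """Observation window for one patient.

    Runs from the study start to the earlier of the patient's death and the
    study end; patients who died after the study end are observed to the
    study end.  A death before the study start means the patient cannot be
    part of the study era at all and is rejected.
    """
    if death_date is None:
        return ObservationWindow(STUDY_START, STUDY_END)
    if death_date < STUDY_START:
        raise ClaimsError(
            f"death date {death_date} precedes study start {STUDY_START}"
        )
    return ObservationWindow(STUDY_START, min(death_date, STUDY_END))


def merge_periods(
    periods: Iterable[tuple[date, date]],
) -> list[tuple[date, date]]:
    """Merge closed day-intervals into disjoint sorted form.

    Abutting periods (end of one = day before start of the next) are merged,
    because membership is whole-day and the union has no gap.
    """
    items = sorted(periods)
    merged: list[list[date]] = []
    for start, end in items:
        if start > end:
            raise ClaimsError(f"period start {start} after end {end}")
        if merged and start <= merged[-1][1] + timedelta(days=1):
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def insurance_coverage_fraction(
    periods: Iterable[tuple[date, date]], window: ObservationWindow
) -> float:
    """Fraction of the observation window covered by insurance periods.

    Inclusive day counting on both ends; periods are merged first, so
    overlapping or split periods never double-count.
    """
    covered = 0
    for start, end in merge_periods(periods):
        lo, hi = max(start, window.start), min(end, window.end)
        if lo <= hi:
            covered += (hi - lo).days + 1
    return covered / window.days


# ---------------------------------------------------------------------------
# Claims bundle: schemas, validation, IO
# ---------------------------------------------------------------------------

PATIENTS_COLUMNS = ["patient_id", "sex", "birth_year", "death_date", "group"]
INSURANCE_COLUMNS = ["patient_id", "start_date", "end_date"]
DIAGNOSES_COLUMNS = [
    "patient_id",
    "icd_code",
    "setting",
    "date",
    "quarter_year",
    "quarter_index",
]
FILLS_COLUMNS = ["patient_id", "atc_code", "fill_date"]
PROCEDURES_COLUMNS = ["patient_id", "ops_code", "date"]

TABLE_COLUMNS: Mapping[str, list[str]] = {
    "patients": PATIENTS_COLUMNS,
    "insurance": INSURANCE_COLUMNS,
    "diagnoses": DIAGNOSES_COLUMNS,
    "fills": FILLS_COLUMNS,
    "procedures": PROCEDURES_COLUMNS,
}

_ICD_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")


@dataclasses.dataclass
class ClaimsBundle:
    """Validated multi-table claims snapshot for one population.

    Attributes are pandas DataFrames with the documented column schemas;
    date columns hold ``datetime.date`` objects (or ``None``), quarter
    fields nullable integers.  Construct via :func:`load_claims_bundle` or
    validate explicitly with :meth:`validate`.
    """

    patients: pd.DataFrame
    insurance: pd.DataFrame
    diagnoses: pd.DataFrame
    fills: pd.DataFrame
    procedures: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}

    def validate(self) -> "ClaimsBundle":
        for name, cols in TABLE_COLUMNS.items():
            df = getattr(self, name)
            for col in cols:
                if col not in df.columns:
                    raise SchemaError(name, None, col, "missing column")

        pat = self.patients
        if pat["patient_id"].duplicated().any():
            dup = pat.loc[pat["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise SchemaError("patients", None, "patient_id", f"duplicate id {dup!r}")
        known = set(pat["patient_id"])
        for i, row in pat.iterrows():
            if row["sex"] not in ("female", "male"):
                raise SchemaError("patients", i, "sex", f"bad value {row['sex']!r}")
            if row["group"] not in ("case_candidate", "control_candidate"):
                raise SchemaError("patients", i, "group", f"bad value {row['group']!r}")
            if not 1900 <= int(row["birth_year"]) <= 2020:
                raise SchemaError(
                    "patients", i, "birth_year", f"{row['birth_year']} outside [1900, 2020]"
                )
            dd = row["death_date"]
            if dd is not None and dd < date(int(row["birth_year"]), 1, 1):
                raise SchemaError("patients", i, "death_date", f"{dd} precedes birth year")

        for name in ("insurance", "diagnoses", "fills", "procedures"):
            df = getattr(self, name)
            orphan = ~df["patient_id"].isin(known)
            if orphan.any():
                i = df.index[orphan][0]
                raise SchemaError(
                    name, i, "patient_id", f"unknown patient {df.loc[i, 'patient_id']!r}"
                )

        for i, row in self.insurance.iterrows():
            if row["start_date"] is None or row["end_date"] is None:
                raise SchemaError("insurance", i, "start_date", "missing date")
            if row["start_date"] > row["end_date"]:
                raise SchemaError(
                    "insurance", i, "end_date",
                    f"start {row['start_date']} after end {row['end_date']}",
                )

        for i, row in self.diagnoses.iterrows():
            if not _ICD_RE.match(str(row["icd_code"])):
                raise SchemaError("diagnoses", i, "icd_code", f"malformed {row['icd_code']!r}")
            has_q = not pd.isna(row["quarter_year"])
            if row["setting"] == "inpatient":
                if row["date"] is None or has_q:
                    raise SchemaError(
                        "diagnoses", i, "date",
                        "inpatient diagnosis requires a date and no quarter",
                    )
            elif row["setting"] == "outpatient":
                if row["date"] is not None or not has_q:
                    raise SchemaError(
                        "diagnoses", i, "quarter_year",
                        "outpatient diagnosis requires a quarter and no date",
                    )
                Quarter(int(row["quarter_year"]), int(row["quarter_index"]))
            else:
                raise SchemaError("diagnoses", i, "setting", f"bad value {row['setting']!r}")

        for i, row in self.fills.iterrows():
            if len(str(row["atc_code"])) < 3:
                raise SchemaError("fills", i, "atc_code", f"too short {row['atc_code']!r}")
            fd = row["fill_date"]
            if fd is None or not STUDY_START <= fd <= STUDY_END:
                raise SchemaError("fills", i, "fill_date", f"{fd} outside study era")

        for i, row in self.procedures.iterrows():
            if row["date"] is None:
                raise SchemaError("procedures", i, "date", "missing date")

        return self


def diagnosis_dates(
    diagnoses: pd.DataFrame,
    midpoint_offset_days: int = QUARTER_MIDPOINT_OFFSET_DAYS,
) -> pd.Series:
    """Resolve every diagnosis row to a calendar date.

    Inpatient rows keep their recorded date; outpatient rows get their
    quarter midpoint.
    """
    out = []
    for _, row in diagnoses.iterrows():
        if row["setting"] == "inpatient":
            out.append(row["date"])
        else:
            out.append(
                Quarter(int(row["quarter_year"]), int(row["quarter_index"])).midpoint(
                    midpoint_offset_days
                )
            )
    return pd.Series(out, index=diagnoses.index, dtype=object)


# -- IO ---------------------------------------------------------------------

_DATE_COLUMNS: Mapping[str, Sequence[str]] = {
    "patients": ["death_date"],
    "insurance": ["start_date", "end_date"],
    "diagnoses": ["date"],
    "fills": ["fill_date"],
    "procedures": ["date"],
}
_INT_COLUMNS: Mapping[str, Sequence[str]] = {
    "patients": ["birth_year"],
    "diagnoses": ["quarter_year", "quarter_index"],
}


def _parse_date(value: str, table: str, row, field: str) -> date | None:
    if value == "":
        return None
    try:
        return date.fromisoformat(value)
    except ValueError as exc:
        raise SchemaError(table, row, field, f"malformed date {value!r}") from exc


def _read_table(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in TABLE_COLUMNS[name]:
        if col not in df.columns:
            raise SchemaError(name, None, col, "missing column")
    for col in _DATE_COLUMNS.get(name, ()):
        df[col] = pd.Series(
            [_parse_date(v, name, i, col) for i, v in df[col].items()],
            index=df.index,
            dtype=object,
        )
    for col in _INT_COLUMNS.get(name, ()):
        df[col] = pd.to_numeric(df[col].replace("", None), errors="raise").astype("Int64")
    return df


def load_claims_bundle(directory: str | Path) -> ClaimsBundle:
    """Load and validate the five claims tables from ``directory``.

    Expects ``patients.csv``, ``insurance.csv``, ``diagnoses.csv``,
    ``fills.csv`` and ``procedures.csv`` with the documented columns;
    empty string means absent.  Raises :class:`SchemaError` naming table,
    row and field on any violation (including referential integrity).
    """
    directory = Path(directory)
    tables = {
        name: _read_table(directory / f"{name}.csv", name) for name in TABLE_COLUMNS
    }
    return ClaimsBundle(**tables).validate()


def write_claims_bundle(bundle: ClaimsBundle, directory: str | Path) -> None:
    """Write the bundle as CSV; dates ISO-formatted, absent values empty."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables().items():
        out = df.copy()
        for col in _DATE_COLUMNS.get(name, ()):
            out[col] = out[col].map(lambda d: "" if d is None else d.isoformat())
        for col in _INT_COLUMNS.get(name, ()):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
        out.to_csv(directory / f"{name}.csv", index=False)
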