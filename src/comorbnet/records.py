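"""Discharge-record ingestion and cohort assembly.

One row of the input file is one hospital admission: an opaque patient id,
sex, birth date, admission/discharge timestamps and the discharge diagnoses
as a separated list of ICD-10 codes (dot form, e.g. ``J18.9``).  Records are
normalised into :class:`PatientRecord` objects, split into the status
asthmaticus (J46) and asthma (J45) cohorts, and same-day stays — which in
this setting are misrouted arrivals rather than true emergencies — can be
excluded.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "ICD10_PATTERN",
    "PatientRecord",
    "Cohort",
    "RecordSchema",
    "SchemaError",
    "RowError",
    "parse_records",
    "write_records",
    "derive_age",
    "derive_los",
    "split_cohorts",
    "filter_zero_day",
    "write_exclusion_report",
]

#: letter + two digits + optional "." + one or two alphanumerics
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[A-Z0-9]{1,2})?$")


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class RowError(ValueError):
    """A row could not be parsed; carries the 0-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


@dataclass(frozen=True)
class PatientRecord:
    """One admission with a deduplicated set of ICD-10 discharge codes."""

    id: str
    sex: str  # "F" or "M"
    birth_date: dt.date
    admission_ts: dt.datetime
    discharge_ts: dt.datetime
    icd_codes: frozenset[str]
    residence: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.discharge_ts < self.admission_ts:
            raise ValueError(
                f"record {self.id}: discharge {self.discharge_ts} precedes "
                f"admission {self.admission_ts}"
            )
        if not self.icd_codes:
            raise ValueError(f"record {self.id}: empty ICD-10 code set")
        for code in self.icd_codes:
            if not ICD10_PATTERN.match(code):
                raise ValueError(f"record {self.id}: invalid ICD-10 code {code!r}")


@dataclass
class Cohort:
    """A labelled list of records with derived age / length-of-stay vectors."""

    label: str  # "J46" or "J45"
    records: list[PatientRecord] = field(default_factory=list)

    @property
    def ages(self) -> list[int]:
        return [derive_age(r) for r in self.records]

    @property
    def lengths_of_stay(self) -> list[int]:
        return [derive_los(r) for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class RecordSchema:
    """Column map for the delimited input file."""

    id: str = "id"
    sex: str = "sex"
    birth_date: str = "birth_date"
    admission: str = "admission"
    discharge: str = "discharge"
    codes: str = "codes"
    lat: str = "lat"
    lon: str = "lon"
    code_separator: str = ";"
    delimiter: str = ","


def _parse_codes(raw: str, sep: str, row: int) -> frozenset[str]:
    codes = frozenset(c.strip().upper() for c in str(raw).split(sep) if c.strip())
    if not codes:
        raise RowError(row, "empty ICD-10 code list")
    return codes


def _parse_ts(raw: object, row: int, column: str) -> dt.datetime:
    try:
        ts = pd.Timestamp(raw)
    except (ValueError, TypeError) as exc:
        raise RowError(row, f"unparseable {column} date {raw!r}") from exc
    if pd.isna(ts):
        raise RowError(row, f"missing {column} date")
    return ts.to_pydatetime()


def parse_records(path, schema: RecordSchema | None = None) -> list[PatientRecord]:
    """Read a delimited records file into :class:`PatientRecord` objects.

    Codes are split on ``schema.code_separator``, trimmed, uppercased and
    deduplicated; row order is preserved.  Missing required columns raise
    :class:`SchemaError`; a bad date or empty code list raises
    :class:`RowError` with the offending 0-based row index.
    """
    schema = schema or RecordSchema()
    df = pd.read_csv(path, sep=schema.delimiter, dtype=str)
    required = [schema.id, schema.sex, schema.birth_date, schema.admission,
                schema.discharge, schema.codes]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    has_geo = schema.lat in df.columns and schema.lon in df.columns
    out: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict() if hasattr(row, "_asdict") else dict(row)
        residence = None
        if has_geo and pd.notna(row.get(schema.lat)) and pd.notna(row.get(schema.lon)):
            residence = (float(row[schema.lat]), float(row[schema.lon]))
        try:
            rec = PatientRecord(
                id=str(row[schema.id]),
                sex=str(row[schema.sex]).strip().upper(),
                birth_date=_parse_ts(row[schema.birth_date], i, schema.birth_date).date(),
                admission_ts=_parse_ts(row[schema.admission], i, schema.admission),
                discharge_ts=_parse_ts(row[schema.discharge], i, schema.discharge),
                icd_codes=_parse_codes(row[schema.codes], schema.code_separator, i),
                residence=residence,
            )
        except RowError:
            raise
        except ValueError as exc:
            raise RowError(i, str(exc)) from exc
        out.append(rec)
    return out


def write_records(records: Iterable[PatientRecord], path,
                  schema: RecordSchema | None = None) -> None:
    """Write records back out in the input schema (normalised form)."""
    schema = schema or RecordSchema()
    rows = []
    for r in records:
        rows.append({
            schema.id: r.id,
            schema.sex: r.sex,
            schema.birth_date: r.birth_date.isoformat(),
            schema.admission: r.admission_ts.isoformat(),
            schema.discharge: r.discharge_ts.isoformat(),
            schema.codes: schema.code_separator.join(sorted(r.icd_codes)),
            schema.lat: r.residence[0] if r.residence else "",
            schema.lon: r.residence[1] if r.residence else "",
        })
    pd.DataFrame(rows).to_csv(path, sep=schema.delimiter, index=False)


def derive_age(r: PatientRecord) -> int:
    """Completed years of life at admission (birthday-aware floor)."""
    adm = r.admission_ts.date()
    if r.birth_date > adm:
        raise ValueError(f"record {r.id}: birth date after admission")
    age = adm.year - r.birth_date.year
    if (adm.month, adm.day) < (r.birth_date.month, r.birth_date.day):
        age -= 1
    return age


def derive_los(r: PatientRecord) -> int:
    """Length of stay in whole calendar days; same-day discharge is 0."""
    return (r.discharge_ts.date() - r.admission_ts.date()).days


def _root(code: str) -> str:
    return code.split(".", 1)[0]


def split_cohorts(
    records: Sequence[PatientRecord],
) -> tuple[Cohort, Cohort, list[PatientRecord]]:
    """Partition records into the J46 cohort, the J45-only cohort, and others.

    J46 membership takes precedence: a record carrying both J46 and J45 codes
    belongs to the status asthmaticus cohort, so the J45 cohort contains just
    the plain-asthma admissions.  The partition is exhaustive and disjoint.
    """
    j46 = Cohort("J46")
    j45 = Cohort("J45")
    other: list[PatientRecord] = []
    for r in records:
        roots = {_root(c) for c in r.icd_codes}
        if "J46" in roots:
            j46.records.append(r)
        elif "J45" in roots:
            j45.records.append(r)
        else:
            other.append(r)
    return j46, j45, other


def filter_zero_day(c: Cohort) -> tuple[Cohort, list[PatientRecord]]:
    """Drop same-day (zero length-of-stay) admissions from a cohort.

    Same-day discharges are not credible for a life-threatening exacerbation
    and are treated as misrouted arrivals; order of the kept records is
    preserved.
    """
    kept = Cohort(c.label)
    removed: list[PatientRecord] = []
    for r in c.records:
        (removed if derive_los(r) == 0 else kept.records).append(r)
    return kept, removed


def write_exclusion_report(removed: Sequence[PatientRecord], path) -> None:
    """Write the excluded record ids and reason as delimited text."""
    pd.DataFrame(
        {"id": [r.id for r in removed],
         "reason": ["zero-day length of stay" for _ in removed]}
    ).to_csv(path, index=False)
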