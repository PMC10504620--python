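"""Domain types for pharmacy/diagnosis claims and strict delimited-text IO.

All stages of the adherence analysis exchange data through three flat CSV
schemas (UTF-8, mandatory header, ISO-8601 dates):

* pharmacy:  ``patient_id,fill_date,days_supply,drug_name``
* diagnosis: ``patient_id,service_date,icd10_code``
* patient:   ``patient_id,sex,age_at_index,state``

ICD-10 codes are stored dot-free and upper-case internally; readers accept
dotted or dot-free input.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, fields as dataclass_fields
from datetime import date
from typing import Iterable, Sequence

__all__ = [
    "PharmacyClaim",
    "DiagnosisClaim",
    "Patient",
    "DRUG_CLASSES",
    "SCHEMAS",
    "normalize_icd10",
    "read_claims",
    "write_claims",
    "ClaimsSchemaError",
    "ClaimsValidationError",
]

#: MOUD drug classes assigned by :func:`oudpdc.cohort.classify_moud`.
DRUG_CLASSES = ("buprenorphine", "naltrexone", "methadone", "other")

_ICD10_RE = re.compile(r"^[A-Z][0-9][0-9A-Z]+$")


class ClaimsSchemaError(ValueError):
    """Raised when a claims file is missing a required column."""


class ClaimsValidationError(ValueError):
    """Raised when one or more rows violate a record invariant.

    Attributes
    ----------
    errors : list of (int, str)
        ``(line_number, message)`` pairs, 1-based including the header line.
    """

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:10])
        extra = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid row(s): {lines}{extra}")


def normalize_icd10(code: str) -> str:
    """Return ``code`` upper-cased with dots and whitespace stripped.

    Idempotent: normalizing an already-normalized code is a no-op.
    """
    return code.strip().replace(".", "").upper()


@dataclass(frozen=True)
class PharmacyClaim:
    """One prescription fill.

    ``drug_class`` is ``None`` on raw claims and set downstream by
    MOUD classification (one of :data:`DRUG_CLASSES`).
    """

    patient_id: str
    fill_date: date
    days_supply: int
    drug_name: str
    drug_class: str | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.days_supply < 1:
            raise ValueError(f"days_supply must be >= 1, got {self.days_supply}")
        if self.drug_class is not None and self.drug_class not in DRUG_CLASSES:
            raise ValueError(f"unknown drug_class {self.drug_class!r}")


@dataclass(frozen=True)
class DiagnosisClaim:
    """One diagnosis code on a claim; ``icd10_code`` must be pre-normalized."""

    patient_id: str
    service_date: date
    icd10_code: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if not _ICD10_RE.match(self.icd10_code):
            raise ValueError(
                f"icd10_code {self.icd10_code!r} is not a normalized ICD-10 code"
            )


@dataclass(frozen=True)
class Patient:
    """Demographics; ``age_at_index`` is age in whole years at the index date."""

    patient_id: str
    sex: str
    age_at_index: int
    state: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not (0 <= self.age_at_index <= 120):
            raise ValueError(f"age_at_index out of [0, 120]: {self.age_at_index}")
        if not self.state:
            raise ValueError("state must be non-empty")


#: column order per schema name
SCHEMAS: dict[str, tuple[str, ...]] = {
    "pharmacy": ("patient_id", "fill_date", "days_supply", "drug_name"),
    "diagnosis": ("patient_id", "service_date", "icd10_code"),
    "patient": ("patient_id", "sex", "age_at_index", "state"),
}

_RECORD_TYPES = {
    "pharmacy": PharmacyClaim,
    "diagnosis": DiagnosisClaim,
    "patient": Patient,
}


def _parse_date(text: str) -> date:
    return date.fromisoformat(text.strip())


def _build_record(schema: str, row: dict[str, str]):
    if schema == "pharmacy":
        return PharmacyClaim(
            patient_id=row["patient_id"].strip(),
            fill_date=_parse_date(row["fill_date"]),
            days_supply=int(row["days_supply"]),
            drug_name=row["drug_name"].strip(),
        )
    if schema == "diagnosis":
        return DiagnosisClaim(
            patient_id=row["patient_id"].strip(),
            service_date=_parse_date(row["service_date"]),
            icd10_code=normalize_icd10(row["icd10_code"]),
        )
    if schema == "patient":
        return Patient(
            patient_id=row["patient_id"].strip(),
            sex=row["sex"].strip().upper(),
            age_at_index=int(row["age_at_index"]),
            state=row["state"].strip(),
        )
    raise ValueError(f"unknown schema {schema!r}")


def read_claims(path, schema: str):
    """Read a claims CSV into a list of typed records.

    Parameters
    ----------
    path : path-like
        CSV file with a header row naming the schema's columns.
    schema : {"pharmacy", "diagnosis", "patient"}

    Raises
    ------
    ClaimsSchemaError
        If a required column is absent from the header.
    ClaimsValidationError
        If any row fails to parse or violates a record invariant; every bad
        row is reported with its 1-based line number.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    columns = SCHEMAS[schema]
    records = []
    errors: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in columns:
            if col not in header:
                raise ClaimsSchemaError(f"missing required column {col!r} in {path}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_build_record(schema, row))
            except (ValueError, KeyError, TypeError) as exc:
                errors.append((lineno, str(exc)))
    if errors:
        raise ClaimsValidationError(errors)
    return records


def write_claims(records: Iterable, path, schema: str | None = None) -> None:
    """Write typed records to a claims CSV (header always written).

    ``schema`` may be omitted when ``records`` is non-empty (inferred from the
    first record); an empty collection requires it so the header can be named.
    Round-trips with :func:`read_claims` field-for-field.
    """
    records = list(records)
    if schema is None:
        if not records:
            raise ValueError("schema is required to write an empty collection")
        for name, typ in _RECORD_TYPES.items():
            if isinstance(records[0], typ):
                schema = name
                break
        else:
            raise ValueError(f"unrecognized record type {type(records[0])!r}")
    columns = SCHEMAS[schema]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        for rec in records:
            writer.writerow([_format(getattr(rec, col)) for col in columns])


def _format(value) -> str:
    if isinstance(value, date):
        return value.isoformat()
    return str(value)


def records_to_frame(records: Sequence):
    """Typed records -> pandas DataFrame (one column per dataclass field)."""
    import pandas as pd

    if not records:
        return pd.DataFrame()
    cols = [f.name for f in dataclass_fields(records[0])]
    return pd.DataFrame({c: [getattr(r, c) for r in records] for c in cols})
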