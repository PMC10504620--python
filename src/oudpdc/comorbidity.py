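"""Elixhauser-style comorbidity flags from ICD-10 prefixes.

Diagnosis histories are condensed into binary comorbidity-category flags via
an editable two-column prefix table (``icd10_prefix,category``). This is a
deliberate table-driven approximation of the full AHRQ Elixhauser algorithm:
it has no exclusion hierarchies, but it is auditable and user-replaceable.
The bundled default covers the five categories that matter for the adherence
model (Alcohol, Drugs, Obesity, FluidsLytes, NeuroOther), e.g. F10/E52 →
Alcohol and the F11–F16 substance family → Drugs.

Matching is longest-prefix-wins: each normalized code contributes the
category of the longest prefix that matches it, or nothing.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .claims import DiagnosisClaim, normalize_icd10

__all__ = [
    "ComorbidityMapping",
    "load_mapping",
    "default_mapping",
    "assign_categories",
    "EXAMPLE_CODES",
    "MappingError",
]

#: one representative (normalized) code per bundled category; used by the
#: claims simulator when it emits comorbidity diagnosis claims.
EXAMPLE_CODES = {
    "Alcohol": "F1020",
    "Drugs": "F1220",
    "Obesity": "E6601",
    "FluidsLytes": "E8770",
    "NeuroOther": "G40909",
}


class MappingError(ValueError):
    """Malformed or inconsistent comorbidity mapping table."""


@dataclass(frozen=True)
class ComorbidityMapping:
    """Validated (prefix -> category) table.

    ``prefixes`` maps each dot-free upper-case prefix to exactly one category;
    ``categories`` is the sorted tuple of distinct category names.
    """

    prefixes: Mapping[str, str]
    categories: tuple[str, ...]

    def category_of(self, code: str) -> str | None:
        """Category of the longest matching prefix, or None."""
        code = normalize_icd10(code)
        best = None
        best_len = -1
        for prefix, cat in self.prefixes.items():
            if len(prefix) > best_len and code.startswith(prefix):
                best, best_len = cat, len(prefix)
        return best


def _build(rows: Iterable[tuple[str, str]], source: str) -> ComorbidityMapping:
    prefixes: dict[str, str] = {}
    seen_rows: set[tuple[str, str]] = set()
    for lineno, (raw_prefix, raw_cat) in enumerate(rows, start=2):
        prefix = normalize_icd10(raw_prefix)
        category = raw_cat.strip()
        if not prefix or not category:
            raise MappingError(f"{source}: malformed row at line {lineno}")
        if (prefix, category) in seen_rows:
            warnings.warn(
                f"{source}: duplicate row ({prefix},{category}) at line {lineno} collapsed",
                stacklevel=2,
            )
            continue
        seen_rows.add((prefix, category))
        if prefix in prefixes and prefixes[prefix] != category:
            raise MappingError(
                f"{source}: prefix {prefix} maps to both "
                f"{prefixes[prefix]!r} and {category!r}"
            )
        prefixes[prefix] = category
    if not prefixes:
        raise MappingError(f"{source}: mapping defines no categories")
    return ComorbidityMapping(
        prefixes=prefixes, categories=tuple(sorted(set(prefixes.values())))
    )


def load_mapping(path) -> ComorbidityMapping:
    """Load and validate a two-column ``icd10_prefix,category`` CSV."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["icd10_prefix", "category"]:
            raise MappingError(f"{path}: expected header 'icd10_prefix,category'")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise MappingError(f"{path}: malformed row at line {lineno}")
            rows.append((row[0], row[1]))
    return _build(rows, str(path))


def default_mapping() -> ComorbidityMapping:
    """The bundled default prefix table."""
    ref = resources.files("oudpdc.data").joinpath("elixhauser_prefixes.csv")
    with resources.as_file(ref) as path:
        return load_mapping(path)


def assign_categories(
    diagnosis_claims: Iterable[DiagnosisClaim],
    mapping: ComorbidityMapping | None = None,
    exclude_prefixes: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Binary comorbidity flags per patient.

    A flag is 1 iff any of the patient's codes resolves (longest prefix) to
    that category; flags are invariant to claim order and multiplicity and
    monotone in the claim set. ``exclude_prefixes`` drops codes in the given
    families before matching — used by the regression design to keep the
    cohort-defining F11 family from turning the Drugs flag on for every
    patient (the F11 burden enters the model separately as a count).

    Returns a DataFrame indexed by patient_id with one 0/1 int column per
    mapping category (all categories present even if never flagged).
    """
    if mapping is None:
        mapping = default_mapping()
    exclude = tuple(normalize_icd10(p) for p in exclude_prefixes)
    flags: dict[str, set[str]] = {}
    for claim in diagnosis_claims:
        code = claim.icd10_code
        if any(code.startswith(p) for p in exclude):
            continue
        cat = mapping.category_of(code)
        if cat is not None:
            flags.setdefault(claim.patient_id, set()).add(cat)
    index = sorted(flags)
    data = {
        cat: [1 if cat in flags[pid] else 0 for pid in index]
        for cat in mapping.categories
    }
    out = pd.DataFrame(data, index=pd.Index(index, name="patient_id"), dtype=int)
    return out
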