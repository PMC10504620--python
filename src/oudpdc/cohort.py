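"""Cohort construction: F11 index events, MOUD classification, eligibility.

The analysis cohort is patients whose first F11-coded claim (opioid abuse /
dependence / unspecified use) falls on or after 2018-01-01 and who have a
PDC score in the month after that index visit, with no missing month between
their first and second scores. The main-analysis cohort additionally
requires scores in all three post-index months; the sensitivity ("all
patients") cohort keeps everyone surviving the exclusions. Every rule is
tallied in a :class:`CohortReport` so the funnel reconstructs the screened
total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .claims import DiagnosisClaim, Patient, PharmacyClaim

__all__ = [
    "IndexEvent",
    "CohortReport",
    "DEFAULT_MOUD_LEXICON",
    "find_index_events",
    "count_f11_codes",
    "classify_moud",
    "build_cohort",
    "treatment_mix",
]

F11_PREFIX = "F11"

#: lowercase substring -> MOUD class; case-insensitive matching.
DEFAULT_MOUD_LEXICON: dict[str, str] = {
    "buprenorphine": "buprenorphine",
    "suboxone": "buprenorphine",
    "subutex": "buprenorphine",
    "zubsolv": "buprenorphine",
    "naltrexone": "naltrexone",
    "vivitrol": "naltrexone",
    "methadone": "methadone",
    "dolophine": "methadone",
    "methadose": "methadone",
}


@dataclass(frozen=True)
class IndexEvent:
    """First F11-coded claim for a patient; anchors the PDC windows."""

    patient_id: str
    index_date: date


@dataclass
class CohortReport:
    """Exclusion funnel and per-patient descriptors.

    ``screened = excluded_pre2018 + excluded_no_month1 + excluded_gap +
    retained`` always holds; ``strata`` counts retained patients by number of
    scored months (1, 2, 3).
    """

    screened: int = 0
    excluded_pre2018: int = 0
    excluded_no_month1: int = 0
    excluded_gap: int = 0
    retained: int = 0
    strata: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    f11_code_count: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.screened != (
            self.excluded_pre2018 + self.excluded_no_month1 + self.excluded_gap + self.retained
        ):
            raise ValueError("funnel counts do not sum to the screened total")
        if sum(self.strata.values()) != self.retained:
            raise ValueError("strata counts do not sum to retained")

    def to_text(self) -> str:
        lines = [
            f"screened: {self.screened}",
            f"excluded_pre2018: {self.excluded_pre2018}",
            f"excluded_no_month1: {self.excluded_no_month1}",
            f"excluded_gap: {self.excluded_gap}",
            f"retained: {self.retained}",
        ]
        for k in (1, 2, 3):
            lines.append(f"stratum_{k}_months: {self.strata.get(k, 0)}")
        return "\n".join(lines) + "\n"


def find_index_events(diagnosis_claims: Iterable[DiagnosisClaim]) -> dict[str, date]:
    """Earliest F11-prefix claim date per patient (prefix match on F11.x).

    Patients with no F11-family code are absent from the result.
    """
    events: dict[str, date] = {}
    for claim in diagnosis_claims:
        if claim.icd10_code.startswith(F11_PREFIX):
            prev = events.get(claim.patient_id)
            if prev is None or claim.service_date < prev:
                events[claim.patient_id] = claim.service_date
    return events


def count_f11_codes(diagnosis_claims: Iterable[DiagnosisClaim]) -> pd.Series:
    """Number of F11-prefix diagnosis claims per patient in the loaded data."""
    counts: dict[str, int] = {}
    for claim in diagnosis_claims:
        if claim.icd10_code.startswith(F11_PREFIX):
            counts[claim.patient_id] = counts.get(claim.patient_id, 0) + 1
    return pd.Series(counts, dtype=int, name="n_f11_codes")


def classify_moud(
    pharmacy_claims: Iterable[PharmacyClaim],
    lexicon: Mapping[str, str] | None = None,
) -> list[PharmacyClaim]:
    """Label each claim's drug class by case-insensitive substring lookup."""
    if lexicon is None:
        lexicon = DEFAULT_MOUD_LEXICON
    if not lexicon:
        raise ValueError("MOUD lexicon must not be empty")
    items = [(k.lower(), v) for k, v in lexicon.items()]
    out = []
    for claim in pharmacy_claims:
        name = claim.drug_name.lower()
        cls = next((v for k, v in items if k in name), "other")
        out.append(
            PharmacyClaim(
                patient_id=claim.patient_id,
                fill_date=claim.fill_date,
                days_supply=claim.days_supply,
                drug_name=claim.drug_name,
                drug_class=cls,
            )
        )
    return out


def build_cohort(
    patients: Sequence[Patient] | pd.DataFrame,
    index_events: Mapping[str, date],
    labeled_claims: Sequence[PharmacyClaim],
    panel: pd.DataFrame,
    diagnosis_claims: Iterable[DiagnosisClaim] | None = None,
    min_index_date: date = date(2018, 1, 1),
) -> tuple[list[str], list[str], CohortReport]:
    """Apply the eligibility rules; returns (main ids, sensitivity ids, report).

    Rules, in order and mutually exclusive per patient:

    1. index before ``min_index_date``  -> excluded_pre2018
    2. no PDC score in month 1          -> excluded_no_month1
    3. month-3 score without a month-2  -> excluded_gap
    4. retained; main cohort = retained with scores in months 1, 2 and 3,
       sensitivity cohort = all retained.
    """
    if isinstance(patients, pd.DataFrame):
        known = set(patients["patient_id"].astype(str))
    else:
        known = {p.patient_id for p in patients}
    in_panel = set(panel["patient_id"].astype(str)) if len(panel) else set()
    orphans = sorted(in_panel - known)
    if orphans:
        raise ValueError(f"panel patients missing demographics: {orphans[:10]}")

    months_by_patient: dict[str, set[int]] = {}
    if len(panel):
        for pid, grp in panel.groupby("patient_id"):
            months_by_patient[str(pid)] = set(int(k) for k in grp["month_index"])

    report = CohortReport(screened=len(index_events))
    main_ids: list[str] = []
    sensitivity_ids: list[str] = []
    for pid in sorted(index_events):
        months = months_by_patient.get(pid, set())
        if index_events[pid] < min_index_date:
            report.excluded_pre2018 += 1
        elif 1 not in months:
            report.excluded_no_month1 += 1
        elif 3 in months and 2 not in months:
            report.excluded_gap += 1
        else:
            report.retained += 1
            report.strata[len(months)] = report.strata.get(len(months), 0) + 1
            sensitivity_ids.append(pid)
            if months == {1, 2, 3}:
                main_ids.append(pid)
    if diagnosis_claims is not None:
        counts = count_f11_codes(diagnosis_claims)
        report.f11_code_count = {
            pid: int(counts.get(pid, 0)) for pid in sensitivity_ids
        }
    report.validate()
    return main_ids, sensitivity_ids, report


def treatment_mix(
    cohort_ids: Sequence[str],
    labeled_claims: Sequence[PharmacyClaim],
    index_events: Mapping[str, date] | None = None,
    window_days: int = 90,
) -> pd.Series:
    """Regimen proportions over cohort patients with >= 1 MOUD-classed fill.

    Regimens: ``bup_only``, ``ntx_only``, ``bup_ntx`` (both observed), and
    ``methadone`` — methadone takes precedence when present alongside other
    classes, mirroring its reporting as a standalone small category. Classes
    are collected from fills within ``window_days`` of the index when index
    events are supplied, otherwise from all fills.
    """
    cohort = set(cohort_ids)
    classes: dict[str, set[str]] = {}
    for claim in labeled_claims:
        if claim.patient_id not in cohort:
            continue
        if claim.drug_class not in ("buprenorphine", "naltrexone", "methadone"):
            continue
        if index_events is not None:
            idx = index_events.get(claim.patient_id)
            if idx is None or not (0 <= (claim.fill_date - idx).days < window_days):
                continue
        classes.setdefault(claim.patient_id, set()).add(claim.drug_class)
    counts = {"bup_only": 0, "ntx_only": 0, "bup_ntx": 0, "methadone": 0}
    for pid, cls in classes.items():
        if "methadone" in cls:
            counts["methadone"] += 1
        elif cls == {"buprenorphine", "naltrexone"}:
            counts["bup_ntx"] += 1
        elif cls == {"buprenorphine"}:
            counts["bup_only"] += 1
        else:
            counts["ntx_only"] += 1
    total = sum(counts.values())
    if total == 0:
        return pd.Series(counts, dtype=float)
    return pd.Series({k: v / total for k, v in counts.items()})
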