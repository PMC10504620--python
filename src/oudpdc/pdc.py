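"""Proportion-of-days-covered (PDC) scoring from pharmacy fill intervals.

PDC for a window is the fraction of its days on which the patient had
medication on hand. Each fill contributes the half-open interval
``[fill_date, fill_date + days_supply)``; overlapping fills of the *same*
drug class are stockpiled (the later fill is shifted to start when the
earlier supply runs out), while different classes never extend one another —
their day-sets are unioned so no day is counted twice.

Months are fixed 30-day windows anchored at the patient's index date
(month ``k`` covers days ``[30(k-1), 30k)`` after the index); a month with
zero covered days yields *no* record rather than a zero score, which is what
makes "missing PDC score" eligibility rules meaningful. A calendar-month
windowing variant is available via ``monthly_pdc(..., window_days=...)``
anchoring choices in the pipeline configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .claims import PharmacyClaim

__all__ = [
    "CoverageInterval",
    "PdcRecord",
    "MonthlySeries",
    "coverage_intervals",
    "covered_days_in",
    "monthly_pdc",
    "pdc_panel",
    "monthly_average_series",
    "PANEL_COLUMNS",
]

#: CSV column order of a PDC panel.
PANEL_COLUMNS = (
    "patient_id",
    "month_index",
    "window_start",
    "window_end",
    "covered_days",
    "pdc",
    "calendar_month",
    "covid",
)


@dataclass(frozen=True)
class CoverageInterval:
    """Half-open date interval during which one drug class is on hand."""

    start: date
    end: date
    drug_class: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval: {self.start} >= {self.end}")


@dataclass(frozen=True)
class PdcRecord:
    """One patient-month adherence score (exists only when covered_days > 0)."""

    patient_id: str
    month_index: int
    window_start: date
    window_end: date
    covered_days: int
    pdc: float
    calendar_month: str
    covid: int


@dataclass(frozen=True)
class MonthlySeries:
    """Calendar-month mean PDC: input of the breakpoint detector.

    months are "YYYY-MM" labels in strictly increasing order (gaps allowed);
    values are the per-month means, counts the contributing record numbers.
    """

    months: tuple[str, ...]
    values: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if list(self.months) != sorted(set(self.months)):
            raise ValueError("months must be strictly increasing")
        if len(self.months) and (np.min(self.values) < 0 or np.max(self.values) > 1):
            raise ValueError("mean PDC values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.months)


def coverage_intervals(
    fills: Sequence[PharmacyClaim], stockpile: bool = True
) -> list[CoverageInterval]:
    """Coverage intervals for one patient's MOUD-classified fills.

    With ``stockpile`` on, a fill whose date falls inside the running
    coverage of the *same* class starts when that coverage ends (early-refill
    supply carried forward). Classes are kept separate here; day-level union
    across classes happens in :func:`covered_days_in`.
    """
    by_class: dict[str, list[PharmacyClaim]] = {}
    for f in fills:
        by_class.setdefault(f.drug_class or "other", []).append(f)
    out: list[CoverageInterval] = []
    for cls, cls_fills in by_class.items():
        end_so_far: date | None = None
        for f in sorted(cls_fills, key=lambda f: (f.fill_date, -f.days_supply)):
            start = f.fill_date
            if stockpile and end_so_far is not None and start < end_so_far:
                start = end_so_far
            end = start + timedelta(days=f.days_supply)
            out.append(CoverageInterval(start, end, cls))
            if end_so_far is None or end > end_so_far:
                end_so_far = end
    out.sort(key=lambda iv: (iv.start, iv.end))
    return out


def _merged_day_ranges(intervals: Iterable[CoverageInterval]) -> list[tuple[int, int]]:
    """Union of intervals across classes as disjoint ordinal-day ranges."""
    spans = sorted((iv.start.toordinal(), iv.end.toordinal()) for iv in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def covered_days_in(
    intervals: Iterable[CoverageInterval], window_start: date, window_end: date
) -> int:
    """Number of days in ``[window_start, window_end)`` covered by any class."""
    ws, we = window_start.toordinal(), window_end.toordinal()
    total = 0
    for s, e in _merged_day_ranges(intervals):
        total += max(0, min(e, we) - max(s, ws))
    return total


def monthly_pdc(
    intervals: Sequence[CoverageInterval],
    index_date: date,
    k: int,
    window_days: int = 30,
    covid_start: str = "2020-03",
    patient_id: str = "",
) -> PdcRecord | None:
    """PDC record for post-index month ``k`` (1..3), or None if uncovered.

    The window is ``[index + window_days*(k-1), index + window_days*k)``;
    the COVID indicator is 1 iff the window's starting calendar month is
    ``covid_start`` ("YYYY-MM") or later.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"month index k must be in {{1, 2, 3}}, got {k}")
    window_start = index_date + timedelta(days=window_days * (k - 1))
    window_end = index_date + timedelta(days=window_days * k)
    covered = covered_days_in(intervals, window_start, window_end)
    if covered == 0:
        return None
    calendar_month = window_start.strftime("%Y-%m")
    return PdcRecord(
        patient_id=patient_id,
        month_index=k,
        window_start=window_start,
        window_end=window_end,
        covered_days=covered,
        pdc=covered / window_days,
        calendar_month=calendar_month,
        covid=int(calendar_month >= covid_start),
    )


def pdc_panel(
    labeled_claims: Sequence[PharmacyClaim],
    index_events: dict[str, date],
    covid_start: str = "2020-03",
    window_days: int = 30,
    stockpile: bool = True,
) -> pd.DataFrame:
    """All existing monthly PDC records (k = 1..3) for every indexed patient.

    Only MOUD-classified fills (``drug_class`` other than "other"/None) count
    toward coverage. Returns a DataFrame with :data:`PANEL_COLUMNS`.
    """
    fills_by_patient: dict[str, list[PharmacyClaim]] = {}
    for claim in labeled_claims:
        if claim.drug_class in ("buprenorphine", "naltrexone", "methadone"):
            fills_by_patient.setdefault(claim.patient_id, []).append(claim)
    rows = []
    for pid in sorted(index_events):
        fills = fills_by_patient.get(pid)
        if not fills:
            continue
        intervals = coverage_intervals(fills, stockpile=stockpile)
        for k in (1, 2, 3):
            rec = monthly_pdc(
                intervals,
                index_events[pid],
                k,
                window_days=window_days,
                covid_start=covid_start,
                patient_id=pid,
            )
            if rec is not None:
                rows.append(rec)
    if not rows:
        return pd.DataFrame(columns=list(PANEL_COLUMNS))
    return pd.DataFrame([r.__dict__ for r in rows], columns=list(PANEL_COLUMNS))


def monthly_average_series(panel: pd.DataFrame) -> MonthlySeries:
    """Unweighted mean PDC per calendar month (records binned by window start).

    Months with no records are omitted; an empty panel yields an empty series.
    """
    if panel.empty:
        return MonthlySeries(months=(), values=np.array([]), counts=np.array([], dtype=int))
    grouped = panel.groupby("calendar_month")["pdc"].agg(["mean", "count"]).sort_index()
    return MonthlySeries(
        months=tuple(grouped.index),
        values=grouped["mean"].to_numpy(float),
        counts=grouped["count"].to_numpy(int),
    )
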