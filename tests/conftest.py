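"""Shared fixtures: a small simulated population, a hand-built 12-patient
eligibility fixture, and a day-by-day pill-stock coverage oracle."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from oudpdc.claims import DiagnosisClaim, Patient, PharmacyClaim
from oudpdc.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """600 simulated patients under the default ground truth (seed 11)."""
    config = SimulationConfig(n_patients=600, seed=11)
    return simulate_population(config)


def day_by_day_covered(fills) -> set[int]:
    """Independent coverage oracle: simulate a per-class pill stock day by day.

    Each day with positive stock of a class is covered and consumes one
    pill of that class; the result is the union of covered day ordinals
    across classes.
    """
    by_class: dict[str, list[PharmacyClaim]] = {}
    for f in fills:
        by_class.setdefault(f.drug_class or "other", []).append(f)
    covered: set[int] = set()
    for cls_fills in by_class.values():
        adds: dict[int, int] = {}
        total = 0
        for f in cls_fills:
            adds[f.fill_date.toordinal()] = adds.get(f.fill_date.toordinal(), 0) + f.days_supply
            total += f.days_supply
        start = min(adds)
        stock = 0
        for day in range(start, max(adds) + total + 1):
            stock += adds.get(day, 0)
            if stock > 0:
                covered.add(day)
                stock -= 1
    return covered


def random_fill_set(rng: np.random.Generator, base=date(2019, 1, 1)) -> list[PharmacyClaim]:
    """1-8 MOUD fills with random dates, supplies and classes."""
    classes = ("buprenorphine", "naltrexone", "methadone")
    n = int(rng.integers(1, 9))
    fills = []
    for _ in range(n):
        fills.append(
            PharmacyClaim(
                patient_id="px",
                fill_date=base + timedelta(days=int(rng.integers(0, 120))),
                days_supply=int(rng.integers(1, 41)),
                drug_name="x",
                drug_class=classes[int(rng.integers(0, 3))],
            )
        )
    return fills


@pytest.fixture(scope="session")
def twelve_patient_fixture():
    """Hand-built cohort exercising every eligibility rule.

    Expected funnel: screened 12; excluded pre-2018 index 2 (p01, p09);
    excluded no-month-1 score 2 (p02 no fills, p03 fills month 2 only);
    excluded month-2 gap 2 (p04, p10: months 1 and 3 only); retained 6 with
    strata {1: 2 (p07, p11), 2: 1 (p06), 3: 3 (p05, p08, p12)}.
    """
    bup = "Buprenorphine-Naloxone SL Film"

    def pharm(pid, idx, months):
        return [
            PharmacyClaim(pid, idx + timedelta(days=30 * (k - 1)), 30, bup)
            for k in months
        ]

    spec = {
        "p01": (date(2017, 12, 15), [1, 2, 3]),
        "p02": (date(2018, 5, 1), []),
        "p03": (date(2018, 6, 1), [2]),
        "p04": (date(2019, 1, 10), [1, 3]),
        "p05": (date(2019, 3, 1), [1, 2, 3]),
        "p06": (date(2019, 7, 4), [1, 2]),
        "p07": (date(2019, 11, 20), [1]),
        "p08": (date(2020, 2, 2), [1, 2, 3]),
        "p09": (date(2016, 1, 1), [1, 2, 3]),
        "p10": (date(2020, 5, 15), [1, 3]),
        "p11": (date(2020, 8, 8), [1]),
        "p12": (date(2020, 10, 1), [1, 2, 3]),
    }
    patients = [
        Patient(pid, "F" if i % 2 else "M", 25 + i, "1")
        for i, pid in enumerate(spec)
    ]
    diagnosis = [DiagnosisClaim(pid, idx, "F1120") for pid, (idx, _) in spec.items()]
    pharmacy = [c for pid, (idx, months) in spec.items() for c in pharm(pid, idx, months)]
    expected = {
        "screened": 12,
        "excluded_pre2018": 2,
        "excluded_no_month1": 2,
        "excluded_gap": 2,
        "retained": 6,
        "strata": {1: 2, 2: 1, 3: 3},
        "main_ids": ["p05", "p08", "p12"],
    }
    return patients, diagnosis, pharmacy, expected
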