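"""Synthetic Medicaid-style claims with known ground truth.

Each simulated patient gets an opioid-use-disorder index event (first
F11-coded diagnosis claim), demographics, comorbidity history, and MOUD
pharmacy fills whose monthly coverage fraction is drawn from a beta law:

    logit(mu_ik) = x_i' beta_true + beta_covid * 1[month-k window starts on
                                                   or after covid_start]
    frac_ik ~ Beta(mu_ik * phi, (1 - mu_ik) * phi)

realized as a single fill at the window start with ``days_supply =
round(30 * frac)`` (no fill when the rounded supply is 0). This one-fill
design makes the latent coverage exactly recoverable by the PDC engine; a
``split_fills`` option instead emits two same-day fills whose supplies sum
to the same total, exercising the stockpiling (shift-forward) logic.
Patients in the 1-/2-month strata stop filling after month 1 or 2.

Default parameters echo the published cohort: coefficient values from the
adherence model's reported table, a 47.4% female share, 6 states, fill-
pattern mix 24.9/24.9/50.2% for 1/2/3+ covered months, and treatment mix
83/12.5/2.6/1.9% for buprenorphine / naltrexone / both / methadone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .betareg import AGE_BANDS, _AGE_COLUMNS
from .claims import DiagnosisClaim, Patient, PharmacyClaim
from .comorbidity import EXAMPLE_CODES

__all__ = ["SimulationConfig", "TruthRecord", "simulate_population", "truth_summary"]


def default_beta_true() -> dict[str, float]:
    """True logit-scale coefficients; defaults echo the published estimates."""
    return {
        "const": 3.203,
        "covid": -0.076,
        "sex_male": -0.023,
        "age_lt16": -0.012,
        "age_30_39": 0.027,
        "age_40_49": 0.044,
        "age_50_59": 0.045,
        "age_ge60": 0.068,
        "state_2": -0.041,
        "state_3": -0.056,
        "state_4": -0.084,
        "state_5": -0.036,
        "state_6": -0.210,
        "elix_NeuroOther": -0.038,
        "elix_Obesity": 0.019,
        "elix_FluidsLytes": -0.034,
        "elix_Alcohol": 0.030,
        "elix_Drugs": -0.011,
    }


_DRUG_NAMES = {
    "buprenorphine": "Buprenorphine-Naloxone SL Film",
    "naltrexone": "Naltrexone HCl 50mg Tab",
    "methadone": "Methadone HCl 10mg",
}
_F11_CODES = ("F1120", "F1110", "F1190")
_F11_PROBS = (0.70, 0.15, 0.15)


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic population.

    ``beta_true`` keys use the regression design's column names (plus
    ``const``); covariates absent from the map have true coefficient 0.
    ``months_covered_mix`` gives P(fill 1 / 2 / 3 months of MOUD);
    ``comorbidity_prevalence`` the marginal probability of each Elixhauser
    flag (realized as one example-coded diagnosis claim when drawn).
    """

    n_patients: int = 1000
    calendar_start: date = date(2018, 1, 1)
    calendar_end: date = date(2021, 3, 31)
    covid_start: str = "2020-03"
    beta_true: dict[str, float] = field(default_factory=default_beta_true)
    phi_true: float = 20.0
    months_covered_mix: tuple[float, float, float] = (0.249, 0.249, 0.502)
    regimen_mix: dict[str, float] = field(
        default_factory=lambda: {
            "bup_only": 0.83,
            "ntx_only": 0.125,
            "bup_ntx": 0.026,
            "methadone": 0.019,
        }
    )
    p_female: float = 0.474
    states: tuple[str, ...] = ("1", "2", "3", "4", "5", "6")
    state_probs: tuple[float, ...] | None = None
    age_band_probs: dict[str, float] = field(
        default_factory=lambda: {
            "<16": 0.01,
            "17-29": 0.30,
            "30-39": 0.35,
            "40-49": 0.20,
            "50-59": 0.10,
            ">=60": 0.04,
        }
    )
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "NeuroOther": 0.08,
            "Obesity": 0.15,
            "FluidsLytes": 0.10,
            "Alcohol": 0.12,
            "Drugs": 0.20,
        }
    )
    extra_f11_rate: float = 2.0
    split_fills: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.phi_true <= 0:
            raise ValueError("phi_true must be > 0")
        if abs(sum(self.months_covered_mix) - 1.0) > 1e-9:
            raise ValueError("months_covered_mix must sum to 1")
        if abs(sum(self.regimen_mix.values()) - 1.0) > 1e-9:
            raise ValueError("regimen_mix must sum to 1")
        for name, p in {**self.comorbidity_prevalence, "p_female": self.p_female}.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {name} out of [0, 1]: {p}")
        if abs(sum(self.age_band_probs.values()) - 1.0) > 1e-9:
            raise ValueError("age_band_probs must sum to 1")
        if set(self.age_band_probs) != set(AGE_BANDS):
            raise ValueError(f"age_band_probs must cover bands {AGE_BANDS}")
        start_m = self.calendar_start.strftime("%Y-%m")
        end_m = self.calendar_end.strftime("%Y-%m")
        if not (start_m <= self.covid_start <= end_m):
            raise ValueError(
                f"covid_start {self.covid_start} outside calendar "
                f"[{start_m}, {end_m}]"
            )

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["calendar_start"] = self.calendar_start.isoformat()
        d["calendar_end"] = self.calendar_end.isoformat()
        return d


@dataclass
class TruthRecord:
    """Ground truth for recovery tests: config echo, break month, and a
    per-patient frame with covariates, stratum, regimen and the latent
    monthly means ``mu_1..mu_3``."""

    config: SimulationConfig
    break_month: str
    patients: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.to_jsonable(),
            "break_month": self.break_month,
            "true_coefficients": self.config.beta_true,
            "phi_true": self.config.phi_true,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def truth_summary(truth: TruthRecord) -> pd.DataFrame:
    """True coefficient table (one row per configured coefficient) plus the
    precision and the true break month."""
    rows = [(k, v) for k, v in truth.config.beta_true.items()]
    rows.append(("phi", truth.config.phi_true))
    rows.append(("break_month", truth.break_month))
    return pd.DataFrame(rows, columns=["name", "value"])


def _index_months(config: SimulationConfig) -> list[date]:
    """First-of-month dates admitting a full 3-month (90-day) follow-up."""
    months = []
    m = date(config.calendar_start.year, config.calendar_start.month, 1)
    while m <= config.calendar_end:
        if date(m.year, m.month, 28) + timedelta(days=90) <= config.calendar_end:
            months.append(m)
        m = (m + timedelta(days=32)).replace(day=1)
    if not months:
        raise ValueError("calendar range admits no index month with 3-month follow-up")
    return months


def simulate_population(
    config: SimulationConfig,
) -> tuple[list[Patient], list[DiagnosisClaim], list[PharmacyClaim], TruthRecord]:
    """Draw a full synthetic population; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    months = _index_months(config)

    # --- covariates, vectorized -------------------------------------------
    pids = [f"p{i:06d}" for i in range(n)]
    male = rng.random(n) >= config.p_female
    band_names = list(config.age_band_probs)
    bands = rng.choice(len(band_names), size=n, p=list(config.age_band_probs.values()))
    band_edges = {"<16": (10, 16), "17-29": (17, 29), "30-39": (30, 39),
                  "40-49": (40, 49), "50-59": (50, 59), ">=60": (60, 75)}
    ages = np.array(
        [rng.integers(*band_edges[band_names[b]], endpoint=True) for b in bands]
    )
    state_probs = config.state_probs or (1 / len(config.states),) * len(config.states)
    states = rng.choice(len(config.states), size=n, p=state_probs)
    comorb = {
        cat: rng.random(n) < p for cat, p in config.comorbidity_prevalence.items()
    }
    month_idx = rng.integers(0, len(months), size=n)
    day_offset = rng.integers(0, 28, size=n)  # day 1..28 keeps follow-up in range
    strata = rng.choice([1, 2, 3], size=n, p=list(config.months_covered_mix))
    regimen_names = list(config.regimen_mix)
    regimens = rng.choice(
        len(regimen_names), size=n, p=list(config.regimen_mix.values())
    )
    n_extra_f11 = rng.poisson(config.extra_f11_rate, size=n)

    # --- latent means ------------------------------------------------------
    bt = config.beta_true
    eta = np.full(n, bt.get("const", 0.0))
    eta += np.where(male, bt.get("sex_male", 0.0), 0.0)
    band_coef = {"<16": "age_lt16", "30-39": "age_30_39", "40-49": "age_40_49",
                 "50-59": "age_50_59", ">=60": "age_ge60"}
    for b, name in enumerate(band_names):
        if name in band_coef:
            eta += np.where(bands == b, bt.get(band_coef[name], 0.0), 0.0)
    for s, level in enumerate(config.states):
        eta += np.where(states == s, bt.get(f"state_{level}", 0.0), 0.0)
    for cat, flag in comorb.items():
        eta += np.where(flag, bt.get(f"elix_{cat}", 0.0), 0.0)

    index_dates = [
        months[mi] + timedelta(days=int(d)) for mi, d in zip(month_idx, day_offset)
    ]
    window_starts = np.array(
        [[idx + timedelta(days=30 * (k - 1)) for k in (1, 2, 3)] for idx in index_dates]
        if n
        else np.empty((0, 3), dtype=object)
    )
    covid = np.array(
        [
            [int(ws.strftime("%Y-%m") >= config.covid_start) for ws in row]
            for row in window_starts
        ]
        if n
        else np.empty((0, 3), dtype=int)
    )
    eta_k = eta[:, None] + bt.get("covid", 0.0) * covid
    mu = expit(eta_k)
    frac = rng.beta(mu * config.phi_true, (1.0 - mu) * config.phi_true) if n else mu
    days = np.rint(30.0 * frac).astype(int)

    # --- claims emission ---------------------------------------------------
    patients: list[Patient] = []
    diagnosis: list[DiagnosisClaim] = []
    pharmacy: list[PharmacyClaim] = []
    f11_draws = rng.choice(len(_F11_CODES), size=max(n, 1) * 16, p=_F11_PROBS)
    f11_cursor = 0

    def next_f11() -> str:
        nonlocal f11_cursor
        code = _F11_CODES[f11_draws[f11_cursor % len(f11_draws)]]
        f11_cursor += 1
        return code

    for i in range(n):
        pid = pids[i]
        idx = index_dates[i]
        patients.append(
            Patient(
                patient_id=pid,
                sex="M" if male[i] else "F",
                age_at_index=int(ages[i]),
                state=config.states[states[i]],
            )
        )
        diagnosis.append(DiagnosisClaim(pid, idx, next_f11()))
        for _ in range(int(n_extra_f11[i])):
            offset = int(rng.integers(1, 90))
            diagnosis.append(DiagnosisClaim(pid, idx + timedelta(days=offset), next_f11()))
        for cat, flag in comorb.items():
            if flag[i]:
                offset = int(rng.integers(-180, 61))
                diagnosis.append(
                    DiagnosisClaim(pid, idx + timedelta(days=offset), EXAMPLE_CODES[cat])
                )
        regimen = regimen_names[regimens[i]]
        for k in (1, 2, 3):
            if k > strata[i]:
                break
            d = int(days[i, k - 1])
            if d == 0:
                continue
            ws = window_starts[i][k - 1]
            pharmacy.extend(_fills_for_month(pid, ws, d, regimen, config.split_fills))

    truth_patients = pd.DataFrame(
        {
            "patient_id": pids,
            "sex": np.where(male, "M", "F"),
            "age_at_index": ages.astype(int) if n else [],
            "age_band": [band_names[b] for b in bands],
            "state": [config.states[s] for s in states],
            "index_date": index_dates,
            "months_covered": strata.astype(int) if n else [],
            "regimen": [regimen_names[r] for r in regimens],
            "n_extra_f11": n_extra_f11.astype(int) if n else [],
            **{f"elix_{cat}": flag.astype(int) for cat, flag in comorb.items()},
            **{f"eta_{k}": eta_k[:, k - 1] for k in (1, 2, 3)},
            **{f"mu_{k}": mu[:, k - 1] for k in (1, 2, 3)},
            **{f"covid_{k}": covid[:, k - 1] for k in (1, 2, 3)},
            **{f"days_{k}": days[:, k - 1] for k in (1, 2, 3)},
        }
    )
    truth = TruthRecord(
        config=config, break_month=config.covid_start, patients=truth_patients
    )
    return patients, diagnosis, pharmacy, truth


def _fills_for_month(
    pid: str, window_start: date, total_days: int, regimen: str, split: bool
) -> list[PharmacyClaim]:
    """Realize one covered month as fills totalling ``total_days`` of supply."""
    if regimen == "bup_ntx" and total_days >= 2:
        # abutting fills of the two classes; day-wise union covers the total
        d1 = (total_days + 1) // 2
        d2 = total_days - d1
        return [
            PharmacyClaim(pid, window_start, d1, _DRUG_NAMES["buprenorphine"]),
            PharmacyClaim(
                pid, window_start + timedelta(days=d1), d2, _DRUG_NAMES["naltrexone"]
            ),
        ]
    drug = {
        "bup_only": "buprenorphine",
        "bup_ntx": "buprenorphine",
        "ntx_only": "naltrexone",
        "methadone": "methadone",
    }[regimen]
    name = _DRUG_NAMES[drug]
    if split and total_days >= 2:
        # two same-day fills: the second must stockpile onto the first
        d1 = (total_days + 1) // 2
        return [
            PharmacyClaim(pid, window_start, d1, name),
            PharmacyClaim(pid, window_start, total_days - d1, name),
        ]
    return [PharmacyClaim(pid, window_start, total_days, name)]
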