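"""PDC engine: interval construction, monthly windows, oracle equivalence."""

from datetime import date, timedelta

import numpy as np
import pytest

from conftest import day_by_day_covered, random_fill_set
from oudpdc.claims import PharmacyClaim
from oudpdc.pdc import (
    coverage_intervals,
    covered_days_in,
    monthly_average_series,
    monthly_pdc,
    pdc_panel,
)

D0 = date(2019, 3, 1)


def fill(day_offset, supply, cls="buprenorphine", pid="p1"):
    return PharmacyClaim(pid, D0 + timedelta(days=day_offset), supply, "x", cls)


class TestCoverageIntervals:
    def test_single_fill_spans_supply(self):
        (iv,) = coverage_intervals([fill(0, 30)])
        assert (iv.start, iv.end) == (D0, D0 + timedelta(days=30))

    def test_stockpile_shifts_same_class_overlap(self):
        ivs = coverage_intervals([fill(0, 10), fill(5, 10)], stockpile=True)
        assert [(iv.start, iv.end) for iv in ivs] == [
            (D0, D0 + timedelta(days=10)),
            (D0 + timedelta(days=10), D0 + timedelta(days=20)),
        ]

    def test_no_stockpile_keeps_raw_dates(self):
        ivs = coverage_intervals([fill(0, 10), fill(5, 10)], stockpile=False)
        assert covered_days_in(ivs, D0, D0 + timedelta(days=30)) == 15

    def test_different_classes_do_not_shift(self):
        ivs = coverage_intervals([fill(0, 10, "buprenorphine"), fill(5, 10, "naltrexone")])
        # union day-wise: [0, 15)
        assert covered_days_in(ivs, D0, D0 + timedelta(days=30)) == 15

    def test_matches_pill_stock_oracle(self):
        """Interval day-sets equal a day-by-day per-class stock simulator."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            fills = random_fill_set(rng)
            ivs = coverage_intervals(fills, stockpile=True)
            expected = day_by_day_covered(fills)
            lo, hi = min(expected), max(expected) + 1
            got = covered_days_in(
                ivs, date.fromordinal(lo), date.fromordinal(hi)
            )
            assert got == len(expected)
            # spot-check sub-windows too
            ws = int(rng.integers(lo, hi))
            we = ws + int(rng.integers(1, 60))
            got_win = covered_days_in(ivs, date.fromordinal(ws), date.fromordinal(we))
            assert got_win == len([d for d in expected if ws <= d < we])

    def test_supply_conservation_under_stockpile(self):
        """Within each class the stockpiled union holds exactly the supplied
        days (nothing lost to overlap, nothing double-counted)."""
        rng = np.random.default_rng(5)
        lo, hi = date(2018, 1, 1), date(2030, 1, 1)
        for _ in range(100):
            fills = random_fill_set(rng)
            ivs = coverage_intervals(fills, stockpile=True)
            total_supply = sum(f.days_supply for f in fills)
            covered_per_class = sum(
                covered_days_in([iv for iv in ivs if iv.drug_class == cls], lo, hi)
                for cls in {f.drug_class for f in fills}
            )
            assert covered_per_class == total_supply


class TestMonthlyPdc:
    def test_full_month_scores_one(self):
        ivs = coverage_intervals([fill(0, 30)])
        rec = monthly_pdc(ivs, D0, 1)
        assert rec.pdc == 1.0 and rec.covered_days == 30

    def test_half_month_then_absent(self):
        ivs = coverage_intervals([fill(0, 15)])
        assert monthly_pdc(ivs, D0, 1).pdc == 0.5
        assert monthly_pdc(ivs, D0, 2) is None

    def test_late_fill_splits_across_windows(self):
        ivs = coverage_intervals([fill(45, 30)])
        assert monthly_pdc(ivs, D0, 1) is None
        assert monthly_pdc(ivs, D0, 2).covered_days == 15
        assert monthly_pdc(ivs, D0, 3).covered_days == 15

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            monthly_pdc([], D0, 4)

    def test_covid_flag_follows_window_start_month(self):
        idx = date(2020, 2, 15)
        ivs = coverage_intervals(
            [PharmacyClaim("p1", idx, 90, "x", "buprenorphine")]
        )
        rec1 = monthly_pdc(ivs, idx, 1)
        rec2 = monthly_pdc(ivs, idx, 2)
        assert (rec1.calendar_month, rec1.covid) == ("2020-02", 0)
        assert (rec2.calendar_month, rec2.covid) == ("2020-03", 1)

    def test_deleting_a_fill_never_raises_pdc(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            fills = random_fill_set(rng)
            ivs_all = coverage_intervals(fills)
            drop = int(rng.integers(0, len(fills)))
            ivs_less = coverage_intervals(fills[:drop] + fills[drop + 1:])
            for k in (1, 2, 3):
                full = monthly_pdc(ivs_all, D0, k)
                less = monthly_pdc(ivs_less, D0, k)
                assert (0 if less is None else less.pdc) <= (
                    0 if full is None else full.pdc
                )


class TestPanelAndSeries:
    def test_panel_matches_simulator_truth(self, small_population):
        """Record count equals the simulator's count of nonzero-coverage
        months, and each record's PDC equals the realized days / 30."""
        from oudpdc.cohort import classify_moud, find_index_events

        patients, diagnosis, pharmacy, truth = small_population
        panel = pdc_panel(classify_moud(pharmacy), find_index_events(diagnosis))
        tp = truth.patients.set_index("patient_id")
        expected = sum(
            int(tp.loc[pid, f"days_{k}"] > 0)
            for pid in tp.index
            for k in (1, 2, 3)
            if k <= tp.loc[pid, "months_covered"]
        )
        assert len(panel) == expected
        merged = panel.merge(tp, left_on="patient_id", right_index=True)
        for k in (1, 2, 3):
            sub = merged[merged["month_index"] == k]
            assert np.allclose(sub["pdc"], sub[f"days_{k}"] / 30.0)

    def test_series_means_and_order(self, small_population):
        from oudpdc.cohort import classify_moud, find_index_events

        patients, diagnosis, pharmacy, _ = small_population
        panel = pdc_panel(classify_moud(pharmacy), find_index_events(diagnosis))
        series = monthly_average_series(panel)
        assert list(series.months) == sorted(series.months)
        month = series.months[len(series) // 2]
        sub = panel[panel["calendar_month"] == month]
        assert np.isclose(series.values[series.months.index(month)], sub["pdc"].mean())
        assert series.counts[series.months.index(month)] == len(sub)

    def test_two_records_average(self):
        import pandas as pd

        panel = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "month_index": [1, 1],
                "pdc": [0.4, 0.6],
                "calendar_month": ["2019-05", "2019-05"],
                "covid": [0, 0],
            }
        )
        series = monthly_average_series(panel)
        assert series.values[0] == pytest.approx(0.5)

    def test_empty_panel_empty_series(self):
        import pandas as pd

        series = monthly_average_series(pd.DataFrame(columns=["patient_id", "pdc", "calendar_month"], index=[]))
        assert len(series) == 0
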