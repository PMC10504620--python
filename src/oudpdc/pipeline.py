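"""End-to-end orchestration: simulate/load -> cohort -> PDC -> breaks -> model.

``run_pipeline`` executes the whole adherence analysis from a single
:class:`PipelineConfig` and writes every artifact (claims CSVs, cohort
funnel, PDC panel, monthly series, breakpoint result and figure, the two
regression tables, a stratified mean-PDC figure, and a manifest with the
seed and config hash) into an output directory. All randomness flows from
``config.seed``: the simulator uses it directly and the breakpoint
bootstrap uses ``seed + 1``, so a rerun with the same config is
reproducible artifact-for-artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .betareg import ModelSpec, RegressionResult, design_matrix, fit_beta_regression
from .breakpoints import MeanShiftBreakpoints
from .claims import read_claims, write_claims
from .cohort import (
    CohortReport,
    build_cohort,
    classify_moud,
    count_f11_codes,
    find_index_events,
    treatment_mix,
)
from .comorbidity import assign_categories, default_mapping, load_mapping
from .pdc import monthly_average_series, pdc_panel
from .simulate import SimulationConfig, simulate_population

__all__ = ["PipelineConfig", "run_pipeline", "report_summary"]

ADHERENCE_THRESHOLD = 0.8  # conventional PDC cut-off for "adherent"


@dataclass
class PipelineConfig:
    """Everything one run needs; see module docstring for seed semantics."""

    simulation: SimulationConfig | None = None
    pharmacy_path: str | None = None
    diagnosis_path: str | None = None
    patient_path: str | None = None
    mapping_path: str | None = None
    covid_start: str = "2020-03"
    window_days: int = 30
    stockpile: bool = True
    m_max: int = 5
    min_segment: int | None = None
    n_boot: int = 999
    block_length: int = 3
    seed: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.simulation is None and not (
            self.pharmacy_path and self.diagnosis_path and self.patient_path
        ):
            raise ValueError(
                "either a simulation block or all three claims paths are required"
            )

    def to_jsonable(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "simulation"}
        d["simulation"] = self.simulation.to_jsonable() if self.simulation else None
        return d


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage; returns the artifact set (also written to ``outdir``)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    # -- inputs ------------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulation is not None:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = SimulationConfig(**{**sim.__dict__, "seed": config.seed})
            patients, diagnosis, pharmacy, truth = simulate_population(sim)
            write_claims(patients, out / "patients.csv", "patient")
            write_claims(diagnosis, out / "diagnosis.csv", "diagnosis")
            write_claims(pharmacy, out / "pharmacy.csv", "pharmacy")
            truth.to_json(out / "truth.json")
            artifacts["truth"] = truth
        else:
            patients = read_claims(config.patient_path, "patient")
            diagnosis = read_claims(config.diagnosis_path, "diagnosis")
            pharmacy = read_claims(config.pharmacy_path, "pharmacy")
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, exc) from exc
    artifacts["patients"] = patients

    patients_df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "sex": [p.sex for p in patients],
            "age_at_index": [p.age_at_index for p in patients],
            "state": [p.state for p in patients],
        }
    )

    stage = "cohort"
    try:
        index_events = find_index_events(diagnosis)
        labeled = classify_moud(pharmacy)
        panel = pdc_panel(
            labeled,
            index_events,
            covid_start=config.covid_start,
            window_days=config.window_days,
            stockpile=config.stockpile,
        )
        main_ids, sensitivity_ids, report = build_cohort(
            patients_df, index_events, labeled, panel, diagnosis_claims=diagnosis
        )
        mix = treatment_mix(sensitivity_ids, labeled, index_events)
        (out / "cohort_report.txt").write_text(report.to_text())
        pd.Series(main_ids, name="patient_id").to_csv(out / "cohort_ids.csv", index=False)
        mix.rename("proportion").to_csv(out / "treatment_mix.csv")
        panel.to_csv(out / "pdc_panel.csv", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    artifacts.update(
        panel=panel,
        cohort_report=report,
        main_ids=main_ids,
        sensitivity_ids=sensitivity_ids,
        treatment_mix=mix,
        index_events=index_events,
    )

    stage = "breakpoints"
    try:
        main_panel = panel[panel["patient_id"].isin(main_ids)]
        series = monthly_average_series(main_panel)
        pd.DataFrame(
            {"month": series.months, "mean_pdc": series.values, "n": series.counts}
        ).to_csv(out / "monthly_series.csv", index=False)
        breaks = None
        if len(series) >= 4:
            detector = MeanShiftBreakpoints(
                m_max=config.m_max,
                min_segment=config.min_segment,
                n_boot=config.n_boot,
                block_length=config.block_length,
                random_state=config.seed + 1,
            )
            breaks = detector.fit(series).result_
            (out / "breakpoints.txt").write_text(_format_breaks(breaks))
            if config.make_plots:
                _plot_series(series, breaks, config.covid_start, out / "figure2.png")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    artifacts.update(series=series, breaks=breaks)

    stage = "regression"
    try:
        mapping = (
            load_mapping(config.mapping_path) if config.mapping_path else default_mapping()
        )
        # the F11 family defines the cohort, so it is excluded from the
        # comorbidity flags (its burden enters as the n_f11_codes count)
        flags = assign_categories(diagnosis, mapping, exclude_prefixes=("F11",))
        f11_counts = count_f11_codes(diagnosis)
        spec_main = ModelSpec(elixhauser=mapping.categories)
        spec_all = ModelSpec(elixhauser=mapping.categories, include_n_months=True)
        X_main, y_main = design_matrix(
            main_panel, patients_df, flags, spec_main, f11_counts
        )
        res_main = fit_beta_regression(X_main, y_main, spec_main)
        all_panel = panel[panel["patient_id"].isin(sensitivity_ids)]
        X_all, y_all = design_matrix(all_panel, patients_df, flags, spec_all, f11_counts)
        res_all = fit_beta_regression(X_all, y_all, spec_all)
        res_main.table.to_csv(out / "regression_main.csv")
        res_all.table.to_csv(out / "regression_all.csv")
        if config.make_plots:
            _plot_strata(panel, artifacts["cohort_report"], sensitivity_ids, out / "figure1.png")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    artifacts.update(regression_main=res_main, regression_all=res_all)

    stage = "manifest"
    config_json = json.dumps(config.to_jsonable(), sort_keys=True)
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "versions": {
            "oudpdc": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = manifest

    report_text = report_summary(artifacts)
    (out / "report.txt").write_text(report_text)
    artifacts["report"] = report_text
    return artifacts


def _format_breaks(res) -> str:
    lines = [f"m_selected: {res.m_selected}"]
    for m in sorted(res.bic_by_m):
        lines.append(f"bic_m{m}: {res.bic_by_m[m]:.6g} (rss {res.rss_by_m[m]:.6g})")
    for i, pos in enumerate(res.break_positions):
        month = res.break_months[i] if res.break_months else str(pos)
        lines.append(f"break_{i + 1}: {month} (boundary index {pos})")
        if res.ci_by_break:
            lo, hi = res.ci_by_break[i]
            lines.append(f"break_{i + 1}_ci: {lo} to {hi}")
    lines.append(
        "segment_means: " + ", ".join(f"{m:.4f}" for m in res.segment_means)
    )
    for w in res.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"


def _plot_series(series, breaks, covid_start: str, path) -> None:
    fig, ax = plt.subplots(figsize=(9, 4))
    x = np.arange(len(series))
    ax.plot(x, series.values, marker="o", ms=3, lw=1, color="black")
    post = [i for i, m in enumerate(series.months) if m >= covid_start]
    if post:
        ax.axvspan(post[0] - 0.5, len(series) - 0.5, color="0.85", zorder=0)
    if breaks is not None:
        for pos in breaks.break_positions:
            ax.axvline(pos - 0.5, ls="--", color="tab:blue")
        for lo, hi in breaks.ci_index_by_break:
            ax.plot([lo - 1, hi - 1], [min(series.values)] * 2, color="red", lw=3)
    step = max(1, len(series) // 13)
    ax.set_xticks(x[::step], [series.months[i] for i in x[::step]], rotation=45, ha="right")
    ax.set_ylabel("mean PDC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_strata(panel: pd.DataFrame, report: CohortReport, cohort_ids, path) -> None:
    sub = panel[panel["patient_id"].isin(set(cohort_ids))]
    n_months = sub.groupby("patient_id")["month_index"].size()
    fig, ax = plt.subplots(figsize=(9, 4))
    for k, label in ((1, "1 month"), (2, "2 months"), (3, "3 months")):
        ids = n_months[n_months == k].index
        strat = sub[sub["patient_id"].isin(ids)]
        if strat.empty:
            continue
        series = strat.groupby("calendar_month")["pdc"].mean().sort_index()
        ax.plot(range(len(series)), series.values, marker="o", ms=2, lw=1, label=label)
    ax.set_ylabel("mean PDC")
    ax.set_xlabel("calendar month")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report_summary(artifacts: dict) -> str:
    """Human-readable run report; notes (rather than fails on) missing parts."""
    sections: list[str] = []

    report: CohortReport | None = artifacts.get("cohort_report")
    if report is not None:
        sections.append("## Cohort funnel\n" + report.to_text())
    else:
        sections.append("## Cohort funnel\n(missing)\n")

    mix = artifacts.get("treatment_mix")
    if mix is not None:
        body = "\n".join(f"{k}: {v:.1%}" for k, v in mix.items())
        sections.append("## Treatment mix\n" + body + "\n")
    else:
        sections.append("## Treatment mix\n(missing)\n")

    panel = artifacts.get("panel")
    if panel is not None and len(panel):
        ids = artifacts.get("sensitivity_ids")
        sub = panel[panel["patient_id"].isin(set(ids))] if ids is not None else panel
        n_months = sub.groupby("patient_id")["month_index"].size()
        lines = []
        for k in (1, 2, 3):
            strat = sub[sub["patient_id"].isin(n_months[n_months == k].index)]
            if len(strat):
                lines.append(f"{k}-month stratum mean PDC: {strat['pdc'].mean():.3f}")
        sections.append("## Mean PDC by months-covered stratum\n" + "\n".join(lines) + "\n")
    else:
        sections.append("## Mean PDC by months-covered stratum\n(missing)\n")

    breaks = artifacts.get("breaks")
    if breaks is not None:
        lines = [f"breaks selected (BIC): {breaks.m_selected}"]
        for i in range(breaks.m_selected):
            month = breaks.break_months[i] if breaks.break_months else breaks.break_positions[i]
            ci = f" (95% CI {breaks.ci_by_break[i][0]} to {breaks.ci_by_break[i][1]})" if breaks.ci_by_break else ""
            lines.append(f"break {i + 1}: {month}{ci}")
        sections.append("## Breakpoints\n" + "\n".join(lines) + "\n")
    else:
        sections.append("## Breakpoints\n(missing)\n")

    res: RegressionResult | None = artifacts.get("regression_main")
    if res is not None:
        c = res.coefficient("covid")
        sections.append(
            "## Pandemic effect (main model)\n"
            f"beta_covid: {c['beta']:.3f} (SE {c['se']:.3f}), "
            f"OR {c['or']:.3f} (95% CI {c['or_ci_low']:.3f}-{c['or_ci_high']:.3f}), "
            f"p {c['p']:.3g}\n"
            f"phi: {res.phi:.2f}, pseudo-R2: {res.pseudo_r2:.3f}, n: {res.n_obs}\n"
        )
    else:
        sections.append("## Pandemic effect (main model)\n(missing)\n")

    if panel is not None and len(panel):
        share = float((panel["pdc"] >= ADHERENCE_THRESHOLD).mean())
        sections.append(
            f"## Adherence\nshare of patient-months with PDC >= "
            f"{ADHERENCE_THRESHOLD}: {share:.1%}\n"
        )
    else:
        sections.append("## Adherence\n(missing)\n")

    return "\n".join(sections)
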