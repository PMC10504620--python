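# oudpdc

Medication-adherence analysis for opioid use disorder (OUD) cohorts built
from pharmacy and diagnosis claims. The package asks a concrete
epidemiological question: *did adherence to medications for opioid use
disorder (MOUD — buprenorphine, naltrexone, methadone) drop when the
COVID-19 pandemic began?* — and provides every stage needed to answer it
reproducibly:

1. **Cohort construction** — the index event is a patient's first
   F11-family ICD-10 claim (opioid abuse F11.1, dependence F11.2,
   unspecified use F11.9). Patients indexed before 2018, without an
   adherence score in the month after the index, or with a gap between
   their first and second scored months are excluded, with a full audit
   funnel.
2. **PDC scoring** — the proportion of days covered for each of the three
   30-day windows after the index: fills span `[fill_date, fill_date +
   days_supply)`, same-class overlapping fills are stockpiled (shifted
   forward), classes are unioned day-wise, and
   `PDC = covered days / 30`. A month with zero coverage has *no* score.
3. **Breakpoint detection** — exact dynamic-programming estimation of
   multiple mean shifts in the monthly mean-PDC series, with the number of
   breaks `m` chosen by minimizing

   `BIC(m) = T·ln(RSS_m/T) + (2m+1)·ln(T)`

   and break-date confidence intervals from a moving-block residual
   bootstrap.
4. **Beta regression** — patient-month PDC in (0,1) modelled as
   `y ~ Beta(μφ, (1−μ)φ)` with `logit(μ) = x'β`, where `x` contains a
   pandemic indicator (1 for windows starting March 2020 or later), age
   band, sex, PDC month, state, F11-claim count, and Elixhauser-style
   comorbidity flags. `exp(β)` are odds ratios on the mean; exact 0/1
   responses are compressed with `y' = (y(N−1)+0.5)/N`.
5. **Synthetic claims** — because real Medicaid claims are proprietary, a
   simulator generates full claims populations with known ground truth
   (latent beta-distributed monthly coverage with a configurable pandemic
   step on the logit scale), so every stage is validated by oracle
   equivalence and parameter recovery.

The two statistical engines are scikit-learn-style estimators
(`BetaRegression`, `MeanShiftBreakpoints`) and compose with sklearn
tooling; the other stages are plain functions over typed claim records and
pandas frames.

## Worked example

```python
from oudpdc.pipeline import PipelineConfig, run_pipeline
from oudpdc.simulate import SimulationConfig

config = PipelineConfig(
    simulation=SimulationConfig(n_patients=10_000),  # defaults echo the study
    seed=1, n_boot=999, make_plots=False,
)
artifacts = run_pipeline(config, "out/")
print(artifacts["report"])
```

prints (abridged):

```
## Treatment mix
bup_only: 83.0%
ntx_only: 12.4%
bup_ntx: 2.6%
methadone: 2.0%

## Breakpoints
breaks selected (BIC): 1
break 1: 2020-01 (95% CI 2019-05 to 2020-07)

## Pandemic effect (main model)
beta_covid: -0.065 (SE 0.018), OR 0.937 (95% CI 0.905-0.970), p 0.00023
phi: 7.38, pseudo-R2: 0.006, n: 14955
```

Reading this: the simulated population carries a true pandemic effect of
−0.076 on the logit of mean adherence starting 2020-03. The pipeline
recovers a significant negative effect (OR < 1 with a CI excluding 1 —
adherence odds fall by ~6% in pandemic months), and the breakpoint detector
places a single mean shift within a couple of months of the true onset.
The point estimate is mildly attenuated relative to the injected −0.076
because realized coverage is rounded to whole days of supply and scores of
exactly 1 are compressed into (0,1) before fitting.

The same stages are available from the shell:

```bash
oudpdc simulate --seed 1 --out sim/
oudpdc pdc --diagnosis sim/diagnosis.csv --pharmacy sim/pharmacy.csv --out panel.csv
oudpdc run-all --config run.yaml --seed 1 --out out/
```

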