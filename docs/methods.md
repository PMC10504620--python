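# Methods

This note documents the models, conventions and defaults behind `oudpdc`,
and what the synthetic-data validation does and does not establish.

## Cohort and eligibility

The index event is the earliest diagnosis claim whose normalized ICD-10
code has prefix `F11` (covering the F11.1 abuse, F11.2 dependence and
F11.9 unspecified-use families; matching is on the dot-free prefix, so any
F11.x subcode qualifies). Eligibility rules are applied in a fixed order
and are mutually exclusive per patient, so the funnel is additive:

1. index date before 2018-01-01 → excluded;
2. no PDC score in the first post-index month → excluded;
3. a month-3 score with no month-2 score (a gap between the first and
   second scored months) → excluded;
4. otherwise retained. The *main* cohort requires scores in all three
   months; the *sensitivity* cohort is every retained patient.

Only the first F11 episode is analyzed; there is no re-indexing after a
gap, and no continuous-enrollment requirement is modelled (enrollment
spans are not part of the input schemas). The "number of F11 codes"
covariate counts all F11-prefix claims for the patient in the loaded data;
no time window is applied — the simplest reproducible definition.

MOUD classification is a case-insensitive substring lexicon over drug
names (buprenorphine/Suboxone/Subutex → buprenorphine, etc.). Regimen
reporting gives methadone precedence when it co-occurs with other classes,
mirroring its role as a small standalone category.

## PDC scoring

A "month" is a fixed 30-day window anchored at the index date: month *k*
covers days `[30(k−1), 30k)` after the index. Anchoring at the visit makes
scores comparable across patients regardless of where in a calendar month
they were indexed. Each fill contributes `[fill_date, fill_date +
days_supply)`. Two conventions matter:

* **Stockpiling.** A fill of a class that begins inside that class's
  running coverage is shifted to start when the existing supply runs out —
  the standard early-refill carry-forward. Different classes never extend
  one another; their day-sets are unioned so a day with two drugs on hand
  counts once. This interval algebra is verified exactly against a
  day-by-day per-class pill-stock simulator on randomized fill sets.
* **Zero-coverage months have no score.** This is required for "missing
  score" eligibility rules and the 1/2/3-month strata to be meaningful.
  `PDC = covered_days / 30 ∈ (0, 1]` whenever a record exists.

The pandemic indicator of a record is 1 iff its window's *starting*
calendar month is 2020-03 or later (the covid-start month is
configurable). No cap is applied to `days_supply`.

## Breakpoint model

The monthly series is the unweighted mean PDC over records binned by
window-start calendar month (an option weights by record counts). The
mean-shift model places `m` boundaries with every segment at least `h`
long, `h = max(2, ceil(0.15·T))` by default — the conventional 15%
trimming. Optimal segmentations are found by dynamic programming over
prefix-sum segment costs; it is exact, and tested against exhaustive
enumeration for all short series on a value grid. Ties break toward the
lexicographically earliest boundaries.

Model order is chosen by `BIC(m) = T·ln(RSS_m/T) + p(m)·ln(T)` with
`p(m) = (m+1) + m` (segment means plus break dates; residual variance
concentrated out), ties to smaller `m`. Conventions for `p(m)` differ
across software; this one is stated explicitly. A property worth knowing:
with this penalty (`2·ln T` per extra break) the selector locates a true
break essentially always, but admits a spurious *additional* break in
roughly 8% of white-noise replicates at `T ≈ 39` — BIC's known mild
overselection for segmentation. The false-positive rate for declaring any
break on a no-break series stays below 10%.

Break-date CIs use a moving-block residual bootstrap (default block 3,
`n_boot` 999): residuals from the fitted step function are resampled in
blocks, added back to the fitted means, and breaks re-estimated with `m`
fixed; the CI is the 2.5/97.5 percentile of each break's position. The
asymptotic break-date distribution would be an alternative; the bootstrap
was chosen because its coverage is directly testable by simulation (and
is, at ~95%). A reported break month is the last month of the old regime.

## Beta regression

Patient-months are treated as independent (no random intercepts), matching
a single-equation beta regression with constant precision:

`y_i ~ Beta(μ_i φ, (1−μ_i) φ)`, `logit(μ_i) = x_i'β`, `φ = exp(ζ)`.

Covariates: pandemic indicator; age band (reference 17–29; ages ≤16 fall
in the youngest band); male sex; PDC month 2/3 (reference month 1); state
dummies (reference first level); F11-claim count; comorbidity flags; plus
the months-of-PDC count in the sensitivity model only (it is constant in
the main cohort). Exact 0/1 responses are compressed with
`y' = (y(N−1)+0.5)/N` before fitting, since observed PDC is often exactly
1. The likelihood is maximized by BFGS with the analytic score from a
least-squares start on the logit scale (method-of-moments start for φ),
gradient tolerance 1e-6, at most 500 iterations; standard errors come from
the inverse observed information (central-difference Jacobian of the
analytic score), inference is Wald-normal (`±1.96·SE`, exponentiated to OR
CIs), and the pseudo-R² is the squared Pearson correlation between the
fitted linear predictor and `logit(y)`. Estimates agree with an
independent beta-regression MLE to ~1e-5 on simulated data, and 95% CI
coverage for the pandemic coefficient is nominal in recovery simulations.

Rank-deficient designs raise an error naming the collinear columns rather
than silently dropping them.

### Comorbidity flags and the Drugs category

Comorbidity mapping is a table-driven longest-prefix match (`icd10_prefix →
category`), deliberately simpler than the full AHRQ algorithm (no
exclusion hierarchies) and user-replaceable. The bundled table covers the
five categories the adherence model uses: Alcohol (F10, E52), Drugs
(F11–F16), Obesity (E66), FluidsLytes (E86/E87/E222), NeuroOther
(G25/G31/G40/G41/R56). Because every cohort member has an F11 claim by
construction, flagging Drugs from the full history would make that column
identically 1 and collinear with the intercept; the regression design
therefore computes flags with the cohort-defining F11 family excluded, so
the Drugs flag reflects *other* substance-use codes (F12–F16) and is
estimable, while the patient's F11 burden enters separately as the claim
count. The shipped mapping itself keeps `F11 → Drugs` for use on general
histories.

## Synthetic-data generator

The simulator emulates the study conditions: patients indexed uniformly
over months admitting a 90-day follow-up within 2018-01 to 2021-03; 47.4%
female; six states (uniform mix); age bands populated with probabilities
(.01, .30, .35, .20, .10, .04) giving a mean age near 37; fill-pattern mix
24.9/24.9/50.2% for 1/2/3 covered months; regimen mix 83/12.5/2.6/1.9%
(buprenorphine / naltrexone / both / methadone); true logit-scale
coefficients defaulting to the published adherence-model estimates
(intercept 3.203, pandemic effect −0.076, male −0.023, age/state/
comorbidity offsets); precision φ = 20 (chosen once as a realistic
within-patient-month dispersion; the published table does not report φ);
comorbidity prevalences .08–.20; Poisson(2) extra F11 claims per patient.

Monthly coverage is drawn from `Beta(μφ, (1−μ)φ)` and realized as a single
fill at the window start with `days_supply = round(30·frac)` — this makes
the latent coverage *exactly* recoverable by the PDC engine, which is the
point: recovery failures then indict the analysis code, not the generator.
A `split_fills` option emits two same-day fills summing to the same supply
to exercise the stockpiling path, and the "both drugs" regimen emits two
abutting fills of different classes to exercise the cross-class union.

What the generator does **not** emulate — and passing tests therefore do
not establish for real claims: multi-fill refill behaviour within a month,
early refills and true stockpiling across months, dropout/enrollment
churn, seasonal or secular adherence trends, state-specific pandemic
timing, stratum-dependent adherence levels (all strata share one latent
model), and measurement problems in days-supply fields. Two known
attenuation mechanisms are visible in end-to-end recovery: rounding
coverage to whole days and compressing exact 1s shrink the fitted pandemic
coefficient by roughly 10–20% relative to the injected truth; direction
and significance are unaffected at the tested sizes.

## Problem sizes and numerical choices

Validation simulations use: 1,000 random fill sets for the PDC oracle;
all grid series to length 6 plus 200 random grid series per length 7–12
for DP exactness; 100 seeds at T=39 for break recovery and bootstrap
calibration (n_boot 199 there; 999 in production runs); 100 datasets of
n=5,000 for regression recovery; and 10,000-patient populations (one with
an injected effect, twenty null replicates) end to end. Segment-cost
comparisons use an absolute tolerance of 1e-9; BIC ties and RSS=0 cases
(BIC −∞) resolve to the smaller model; the bootstrap percentile uses
nearest-rank months. Seeds are explicit everywhere; a pipeline run's seed
drives the simulator directly and the bootstrap via `seed + 1`.
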