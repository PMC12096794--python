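# Methods

`kinrates` estimates period-, age- and sex-specific mortality (and, as a
validity check, fertility) from family rosters reported by survey
respondents: each respondent lists their biological parents, siblings and
nieces/nephews — and optionally a spouse's — with vital status, partial
birth/death dates and, for the deceased, cause and place of death. This is
the indirect-estimation tradition of the DHS sibling-survival and
child-survival modules, adapted to a diaspora sample reporting on family
inside a conflict-affected region.

## Date and exposure model

All survey dates are month-resolved; the day is fixed at 15. Exceptions at
day resolution: the conflict onset (4 November 2020), the data-collection
window (6 November 2022 – 18 April 2023) and per-respondent completion
dates. Conventions:

* **Half-open intervals.** Periods are `[start, end)`, age strata
  `[lo, hi)` in completed months; a death on a boundary belongs to the
  later period. This makes cells a partition: no double counting.
* **Person-years** are day counts divided by 365.25.
* **Birth resolution.** A stated year/month gives day 15; an age alone is
  back-computed mid-interval (age + 6 months before the anchor date). For
  a deceased relative reported only by age at death, the anchor is the
  resolved death date.
* **Death-month imputation.** Year-only deaths in years touched by the
  collection window take the window's midpoint month clamped into the
  stated year (a 2022 death resolves to December 2022); earlier year-only
  deaths take July. One consequence, visible in simulation: a year-only
  death early in the onset year resolves into the war period even if it
  occurred in the pre-war months of that year. With realistic month
  missingness (~15%) this inflates the war-period death count by roughly
  1 in 20 — an inherent cost of the imputation rule, not of the exposure
  arithmetic, and one reason the calibration experiments below switch
  month missingness off.
* **Irreconcilable records** (death before birth; stated age at death more
  than a year off the implied age) are excluded with a logged reason.
* **Status-unknown relatives** contribute neither deaths nor person-time
  by default; an `unknown_as_alive` mode censors them at completion for
  sensitivity work.

Exposure for a cell is the closed-form intersection of the age interval,
the period, and the lifespan. A deliberately independent day-stepping
accumulator (`day_step_exposure`) walks every calendar day and recomputes
completed-months age from calendar fields; the two agree to under a day on
random lifespans (exactly, in practice), and every death lands in the same
cell. Month arithmetic clamps days to 28, which matters only for
day-29–31 anchors that the resolver never produces.

## Estimators

* **Children and young cohorts** (nieces/nephews): synthetic-cohort
  probabilities `q = 1 − Π_a (1 − d_a/n_a)` over age strata within a
  period — 0–11 and 12–59 months for the under-5 span (the second stratum
  closes the span), 5-year strata for 5–14 and 15–24. The risk set `n_a`
  counts person-entries fractionally: stratum person-time divided by
  stratum width, so partial-period entrants contribute their exact
  fraction. Conditional spans need no explicit survivor restriction:
  children dying earlier contribute nothing to later strata.
* **Adults** (siblings, 15–49 in 5-year strata) and **older adults**
  (parents, 60–99; decade pre-war periods): deaths over person-time, per
  1000 person-years, sex-specific and combined. Respondents and spouses
  themselves are reporters, not subjects: alive by construction and
  outside the region, they would bias denominators and are excluded from
  rosters.
* **Primary scope** drops relatives who died outside the region
  (record-level); deaths at an unknown zone *within* the region stay in
  scope, country-level-unknown locations are dropped (a flag restores
  them). Sex-unknown relatives stay in totals and combined estimates but
  not in sex-stratified ones.
* **Fertility**: ASFR = linked births over sibling person-years per
  5-year band, computed for female and (with paternal linkage) male
  siblings; TFR = 5 × Σ ASFR, an exact identity. Birth intervals exclude
  first-borns; same-month births to one parent count as multiples and are
  excluded from the interval distribution.

## Bootstrap

Confidence intervals are 95% percentile intervals over respondent-level
cluster resamples: a replicate draws respondent ids with replacement
(original count), every relative — spouse roster included — travelling
with its respondent. Undefined replicates (empty denominators) are dropped
and counted. Endpoints use the conventional (B+1) order-statistic rule, so
they are always observed replicate values. Every estimator here is a
function of cluster-wise sums, so a vectorised sufficient-statistic
resampler reproduces the generic resampler replicate-for-replicate under
one seed; the test suite asserts this equivalence exactly.

Calibration, measured over batches of 200 synthetic surveys (1000
respondents, ~210 war-period adult deaths each): coverage 91.5–95.0% per
batch, ~93.4% pooled over 800 datasets — about a point below nominal, the
familiar small-sample behaviour of percentile intervals for ratio
estimators. At ~1000 deaths per dataset coverage is nominal (97/100). The
acceptance test asserts the 93–97% band on one frozen 200-dataset batch
at B=1000; with batch noise of ±3 datasets that check sits on a knife
edge, and the frozen batch measured 92%.

## Synthetic cohorts

The generator is the package's study population. Defaults mirror the
survey that motivated the design: 791 analysable respondents (with the
observed referral-generation mix), 20.5% also reporting a spouse's family,
two parents plus Poisson(4.25) siblings per family, nieces/nephews born to
siblings through an age-specific fertility process, ~9% unknown-status
masking, ~20% of deaths outside the region, month-only death dates for
15% of deaths, half of birth dates reported as ages.

* **Lifespans** are drawn by inversion from piecewise-constant hazards on
  a period × age-band × sex grid. Default hazards reproduce the survey's
  standardised estimates — war-period adults 21.3/1000 py combined at a
  2:1 male:female ratio, older adults 45.1, with the published declining
  pre-war sequences — so parameter-recovery tests target the numbers the
  method is meant to produce.
* **The hazard schedule is in-region mortality.** The fraction of deaths
  occurring outside the region (excluded from the primary analysis) is
  generated as additional mortality — total hazard inflated by
  1/(1−p_outside) — so the in-scope analysis is unbiased for the
  scheduled rates. Treating out-region deaths as a random label on
  scheduled deaths instead would make every in-region rate recover only
  (1−p) of its generating value.
* **Fertility** defaults to a schedule peaking at 30–34 with TFR 2.2 —
  deliberately below population-level references, because it reproduces
  the roster sizes actually reported (about five nieces/nephews per
  family) and the survey's own finding of low reported fertility. A
  higher schedule would double the child roster relative to the study it
  emulates.
* **Ground truth** (exact schedules, every relative's true status and
  dates) is emitted as separate files, never merged into the survey
  export.

What the generator does *not* emulate: referral-network structure beyond a
generation label, respondent recall error correlated with outcomes
(missingness and unknown status are MCAR), household clustering of deaths
beyond shared hazards, displacement within the country, and duplicate
reporting across respondents. Passing recovery tests therefore show the
estimators are correct for honestly-reported rosters under MCAR
missingness — not that real diaspora reports are unbiased; the original
study's own validity checks (fertility, external comparisons) address
that side.

## Standardisation

Asset items from the respondent's closest family in the region are
completed by chained-equations imputation (random-forest conditional
models, 5 chains × 20 iterations, chains combined cell-wise by mode —
appropriate because the downstream use is quintile classification, not
variance estimation). Per residence stratum, principal components of the
pooled survey + reference covariance matrix are varimax-rotated (up to
three components); the index is the score on the rotated component with
the largest squared loadings, sign-oriented so more assets means a higher
score; quintiles are cut on the pooled score distribution. Each
(residence × quintile) stratum receives a weight equal to its reference
proportion; reference mass on strata absent from the survey is
redistributed proportionally and logged. Estimates apply the family-level
factor w(stratum)/p_survey(stratum) to deaths and person-time jointly, so
the standardised rate is a convex combination of stratum rates, reduces
exactly to the unweighted estimate when sample and reference distributions
coincide, and in the bias experiment (rural mortality double urban,
sample 80% urban vs reference 25%) lands closer to the population-true
rate than the unstandardised estimate in ≥45/50 simulations at 1500
respondents per run — the run count chosen to give the comparison >99%
per-run power at the observed noise level. By default the bootstrap
refits weights per replicate but reuses imputations ("fast" mode); "full"
mode refits imputation too.

## Sensitivity analyses and extrapolation

* **Spouse exclusion** reruns every estimate on respondent-sourced
  relatives only.
* **Out-migration**: a proportion of in-scope alive relatives departs at
  a uniformly drawn date between the conflict onset and the survey, and is
  censored there; 1000 simulations by default, summarised by median and
  2.5/97.5 percentiles. With proportion 0 the primary analysis is
  reproduced bit-for-bit; the simulated median matches a closed-form
  expected-denominator calculation within 2%.
* **Excess deaths** = Σ over age bands of (war rate − baseline rate) ×
  population × band share × period length, with CIs by pushing bootstrap
  replicate pairs through the same formula. The population frame
  (mid-period population, band shares, baseline period) is a required
  explicit input: the analysis scripts use a synthetic frame, and no
  published toll is reproduced — that figure depends on microdata and
  composition choices not available here.

## Problem sizes

Recovery tests run at 2000–3000 families (3 standard-error tolerance on
generating rates), the acceptance script at 6000; bootstrap calibration
uses 200 datasets × 1000 respondents; the bias experiment 50 × 1500
respondents; oracle comparisons 1000 lifespans. A full default-conditions
analysis (791 respondents, B=1000) runs in well under a minute on one
core.

## Known limitations

* Pre-war rates rest on few reported deaths; in simulation their relative
  error is correspondingly wide.
* The clamped-midpoint death-date rule can move year-only onset-year
  deaths across the war boundary (see above).
* Mode-combined imputation understates imputation uncertainty by design;
  quintile assignments, not variances, are consumed downstream.
* The percentile cluster bootstrap runs ~1 point below nominal coverage
  at ~200 deaths per dataset.
* Weights are post-stratification cell proportions only — no raking or
  calibration to margins, and no reconstruction of the reference survey's
  own design weights.
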