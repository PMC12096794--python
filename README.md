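# kinrates

Indirect mortality and fertility estimation from kinship-survey data —
family rosters (parents, siblings, nieces/nephews) reported by survey
respondents, as collected by DHS-style sibling- and child-survival modules
and by diaspora surveys of populations that cannot be surveyed directly.
It is written for epidemiologists and demographers who need period-,
age- and sex-specific mortality from such rosters, with honest uncertainty
and explicit handling of the partial dates, unknown statuses and selection
bias these instruments produce.

## What it computes

**Exposure.** Every relative's reported fields are resolved to a lifespan
(month resolution, day 15; ages placed mid-interval; year-only death
months imputed by the collection-window midpoint clamped into the death
year). Person-time in each period × age-stratum × sex cell is the exact
day-count intersection of the lifespan, the age band and the period —
`[birth+lo, birth+hi) ∩ [t0, t1) ∩ [birth, end)` — divided by 365.25,
with half-open conventions throughout.

**Child and young-cohort mortality** (from nieces/nephews) uses the
synthetic-cohort construction

    q = 1 − Π_a (1 − d_a / n_a)        (reported per 1000)

over age strata *a* within a period, with `n_a` the fractional risk set
(stratum person-time over stratum width). Spans: under-5 (0–11, 12–59
months), 5–14 and 15–24 (conditional on surviving to the span).

**Adult and older-adult mortality** (from siblings aged 15–49 and parents
aged 60–99) is the classic occurrence/exposure rate `1000 × ΣD / ΣPY`,
by sex and combined, over the analysis periods (three pre-war periods and
the conflict period for adults; decade periods back to 1980 for parents).

**Uncertainty** is a 95% percentile interval over respondent-level
cluster bootstrap resamples (all of a respondent's relatives travel
together, spouse roster included).

**Standardisation.** An asset-based wealth index (PCA on the pooled
survey + reference covariance matrix, varimax rotation, first rotated
component) is built per urban/rural stratum; missing items are completed
by chained-equations imputation with random-forest models. Each
residence × wealth-quintile stratum gets a post-stratification weight
equal to its reference-sample proportion, applied jointly to deaths and
person-time.

**Sensitivity and extrapolation.** Spouse-roster exclusion; simulated
pre-survey out-migration of reportedly-alive relatives (uniform departure
dates, 1000 simulations); and a crude excess-death extrapolation
`Σ_bands (rate_war − rate_baseline) × population × share × years`.

**Synthetic cohorts.** Because real rosters of this kind are rarely
shareable, the package ships a generator that simulates whole surveys —
family structures, piecewise-constant-hazard lifespans, an age-specific
fertility process for linked births, reporting noise and a reference
sample — with ground truth emitted separately, so every estimator is
testable against known rates. Defaults encode the study conditions the
package was built around (see `docs/methods.md`).

## Worked example

```python
from kinrates import SimConfig, generate_survey
from kinrates.exposure import resolve_dates, standard_periods
from kinrates.ingest import completion_series, filter_death_location_scope
from kinrates.estimators import rate_with_ci

cfg = SimConfig(n_respondents=1000, seed=7)     # default study conditions
respondents, relatives, truth = generate_survey(cfg)

resolved = filter_death_location_scope(          # primary scope: in-region deaths
    resolve_dates(relatives, completion_series(respondents))
)
siblings = resolved[resolved["relation"] == "sibling"]
war = standard_periods()[-1]                     # Nov 2020 - Apr 2023

r = rate_with_ci(respondents, siblings, war, age_range_years=(15, 50), B=1000, seed=7)
print(f"war-period adult mortality: {r.rate_per_1000py:.1f} per 1000 py "
      f"(95% CI {r.ci_lo:.1f}-{r.ci_hi:.1f}; {r.deaths:.0f} deaths / {r.person_years:.0f} py)")
```

prints

```
war-period adult mortality: 22.0 per 1000 py (95% CI 19.0-25.1; 194 deaths / 8822 py)
```

The generator drew adult wartime mortality at 21.3 per 1000 person-years
(2:1 male:female); the estimate recovers it within sampling error, and the
interval is a percentile interval over 1000 respondent resamples. The
`truth` dict holds the exact hazard and fertility schedules used plus each
relative's true status, for validation.

## The analysis

Numbered drivers under `analysis/` run the full study on a synthetic
survey and write tidy tables under `results/`:

1. `01_simulate_survey.py` — generate the working survey + reference sample
2. `02_tabulate_survey.py` — attrition cascade, roster and cause-of-death
   tables (also recomputed from the packaged published-aggregate fixture)
3. `03_estimate_mortality.py` — child/adult/older-adult estimates with CIs
4. `04_fertility_checks.py` — ASFR, TFR and birth-interval diagnostics
5. `05_standardise_estimates.py` — wealth index, weights, standardised rates
6. `06_sensitivity_excess.py` — spouse exclusion, out-migration, excess toll

A `kinrates` CLI (`simulate`, `ingest`, `estimate`, `fertility`,
`standardise`, `sensitivity`, `excess`, `run`) wraps the same library for
shell use; `kinrates run --config cfg.yaml` executes the configured
pipeline end-to-end and writes a manifest.

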