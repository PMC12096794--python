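"""Mortality estimators: synthetic-cohort probabilities, period rates,
respondent-cluster bootstrap."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from kinrates.config import flat_hazard_config
from kinrates.estimators import (
    bootstrap_ci,
    child_mortality,
    child_mortality_with_ci,
    cluster_bootstrap,
    period_rate,
    period_rate_reduce,
    q_from_strata,
    rate_from_resolved,
    rate_with_ci,
)
from kinrates.exposure import Period, resolve_dates, standard_periods
from kinrates.ingest import completion_series
from kinrates.synthetic import generate_survey

WAR = standard_periods()[-1]


def _strata(cells):
    return pd.DataFrame(
        [{"age_lo_m": 0, "age_hi_m": 12, "deaths": d, "n_risk": n} for d, n in cells]
    )


class TestSyntheticCohortProbability:
    def test_zero_deaths_zero_probability(self):
        assert q_from_strata(_strata([(0, 100), (0, 50)])) == 0.0

    def test_single_stratum_reduces_to_ratio(self):
        assert q_from_strata(_strata([(1, 100)])) * 1000 == pytest.approx(10.0)

    def test_two_stratum_hand_product(self):
        q = q_from_strata(_strata([(2, 200), (1, 150)]))
        assert q == pytest.approx(1 - (1 - 2 / 200) * (1 - 1 / 150), abs=1e-12)
        assert round(q * 1000, 1) == 16.6

    def test_exhaustive_cohort_enumeration_oracle(self):
        """A fully-followed cohort: q equals the share dying within the
        span, enumerated child by child."""
        n = 200
        period = Period("p", dt.date(2010, 1, 1), dt.date(2020, 1, 1))
        rows = []
        rng = np.random.default_rng(12)
        died_flags = rng.random(n) < 0.06
        death_ages_m = rng.integers(1, 59, n)
        for i in range(n):
            birth = pd.Timestamp("2011-03-15")
            if died_flags[i]:
                death = birth + pd.DateOffset(months=int(death_ages_m[i]))
                rows.append({"birth": birth, "end": death, "death_date": death,
                             "died": True, "include": True, "sex": "female"})
            else:
                rows.append({"birth": birth, "end": pd.Timestamp("2023-01-15"),
                             "death_date": pd.NaT, "died": False, "include": True, "sex": "female"})
        resolved = pd.DataFrame(rows)
        est = child_mortality(resolved, period, "U5")
        enumerated = died_flags.mean()
        # agreement within the fractional-risk-set approximation (partial
        # entrants); for a cohort fully inside the period this is tight
        assert est.q_per_1000 / 1000 == pytest.approx(enumerated, abs=0.01)

    def test_monotone_in_deaths(self):
        q1 = q_from_strata(_strata([(2, 200), (1, 150)]))
        q2 = q_from_strata(_strata([(3, 200), (1, 150)]))
        assert q2 > q1

    def test_empty_risk_set_flagged_undefined(self):
        resolved = pd.DataFrame(
            {"birth": [pd.Timestamp("1950-01-15")], "end": [pd.Timestamp("2023-01-15")],
             "death_date": [pd.NaT], "died": [False], "include": [True], "sex": ["male"]}
        )
        est = child_mortality(resolved, WAR, "U5")
        assert est.undefined

    def test_unknown_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            child_mortality(pd.DataFrame(), WAR, "U99")


class TestPeriodRate:
    def _ledger(self):
        return pd.DataFrame(
            [
                {"period": "war", "age_lo_m": 180, "age_hi_m": 600, "sex": "male",
                 "person_years": 150.0, "deaths": 4},
                {"period": "war", "age_lo_m": 180, "age_hi_m": 600, "sex": "female",
                 "person_years": 100.0, "deaths": 1},
            ]
        )

    def test_simple_ratio(self):
        r = period_rate(self._ledger(), "war", (15, 50))
        assert r.rate_per_1000py == pytest.approx(1000 * 5 / 250)

    def test_combined_rate_is_persontime_weighted_mix(self):
        led = self._ledger()
        rm = period_rate(led, "war", (15, 50), "male")
        rf = period_rate(led, "war", (15, 50), "female")
        rall = period_rate(led, "war", (15, 50))
        w = 150 / 250
        assert rall.rate_per_1000py == pytest.approx(w * rm.rate_per_1000py + (1 - w) * rf.rate_per_1000py)

    def test_zero_person_years_flagged(self):
        led = self._ledger().assign(person_years=0.0, deaths=0)
        r = period_rate(led, "war", (15, 50))
        assert r.undefined

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError, match="no cells"):
            period_rate(self._ledger(), "1990s", (15, 50))

    @pytest.mark.parametrize("hazard", [0.001, 0.005, 0.020, 0.045])
    def test_recovery_across_hazard_grid(self, hazard):
        """Bias of the rate estimator < 3 SE (and small in relative terms at
        the higher hazards) across the plausible hazard range."""
        cfg = flat_hazard_config(
            hazard, n_respondents=3000, seed=int(hazard * 1e6) % 1000,
            outside_tigray_prob=0.0, unknown_status_prob=0.0,
        )
        respondents, relatives, _ = generate_survey(cfg)
        resolved = resolve_dates(relatives, completion_series(respondents))
        r = rate_from_resolved(resolved, WAR, (15, 50))
        se = 1000 * np.sqrt(max(r.deaths, 1)) / r.person_years
        assert abs(r.rate_per_1000py - 1000 * hazard) < 3 * se


@pytest.fixture(scope="module")
def boot_data():
    cfg = flat_hazard_config(0.02, n_respondents=250, seed=31)
    respondents, relatives, _ = generate_survey(cfg)
    resolved = resolve_dates(relatives, completion_series(respondents))
    return respondents, relatives, resolved


class TestBootstrap:
    def test_rejects_invalid_replicate_count(self, boot_data):
        respondents, relatives, _ = boot_data
        with pytest.raises(ValueError, match="B"):
            bootstrap_ci(lambda r, x: 0.0, respondents, relatives, B=0)

    def test_single_respondent_degenerate_interval(self, boot_data):
        respondents, relatives, _ = boot_data
        one = respondents.iloc[:1]
        rel = relatives[relatives["respondent_id"] == one["respondent_id"].iloc[0]]
        est = lambda resp, r: float(len(r))
        ci = bootstrap_ci(est, one, rel, B=50, seed=0)
        assert ci.lo == ci.hi == len(rel)

    def test_seed_determinism(self, boot_data):
        respondents, relatives, _ = boot_data
        est = lambda resp, r: float((r["status"] == "deceased").mean())
        a = bootstrap_ci(est, respondents, relatives, B=60, seed=7)
        b = bootstrap_ci(est, respondents, relatives, B=60, seed=7)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_endpoints_are_order_statistics(self, boot_data):
        respondents, relatives, _ = boot_data
        est = lambda resp, r: float((r["status"] == "deceased").mean())
        ci = bootstrap_ci(est, respondents, relatives, B=101, seed=3)
        reps = np.sort(ci.replicates[np.isfinite(ci.replicates)])
        assert ci.lo in reps and ci.hi in reps
        assert ci.lo <= np.median(reps) <= ci.hi

    def test_generic_and_vectorised_paths_agree_exactly(self, boot_data):
        """For a cluster-sum estimator the generic resampler and the
        vectorised sufficient-statistic bootstrap draw identical replicates
        under one seed."""
        from kinrates.estimators import respondent_sums
        from kinrates.exposure import AgeStratum, cell_exposure

        respondents, relatives, resolved = boot_data
        py, dth = cell_exposure(resolved, WAR, AgeStratum(180, 600))
        aug = resolved.assign(_py=py, _d=dth.astype(float))

        def est(resp, rel):
            p = rel["_py"].sum()
            return 1000.0 * rel["_d"].sum() / p if p > 0 else np.nan

        generic = bootstrap_ci(est, respondents, aug, B=40, seed=11)
        stats = respondent_sums(resolved, respondents, np.column_stack([py, dth.astype(float)]))
        fast = cluster_bootstrap(stats, period_rate_reduce, B=40, seed=11)
        np.testing.assert_allclose(generic.replicates, fast.replicates, rtol=1e-10)

    def test_rate_with_ci_brackets_point_estimate(self, boot_data):
        respondents, _, resolved = boot_data
        r = rate_with_ci(respondents, resolved, WAR, (15, 50), B=200, seed=5)
        assert r.ci_lo <= r.rate_per_1000py <= r.ci_hi
        assert r.deaths > 0

    def test_child_ci_brackets_point_estimate(self, boot_data):
        respondents, _, resolved = boot_data
        kids = resolved[resolved["relation"] == "niece_nephew"]
        e = child_mortality_with_ci(respondents, kids, WAR, "U5", B=200, seed=5)
        if not e.undefined:
            assert e.ci_lo <= e.q_per_1000 + 1e-9
            assert e.q_per_1000 <= e.ci_hi + 1e-9
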