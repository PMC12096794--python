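"""Spouse exclusion, out-migration simulation, excess-death extrapolation."""

import numpy as np
import pandas as pd
import pytest

from kinrates.dates import date_to_day
from kinrates.estimators import rate_from_resolved
from kinrates.exposure import WAR_START, resolve_dates, standard_periods
from kinrates.ingest import assemble_rosters, completion_series, filter_death_location_scope
from kinrates.sensitivity import (
    MigrationScenario,
    PopulationFrame,
    excess_deaths,
    migration_sensitivity,
    spouse_exclusion,
    summarise_migration,
)

WAR = standard_periods()[-1]


class TestSpouseExclusion:
    def test_no_spouse_rosters_means_zero_deltas(self, small_survey):
        _, respondents, relatives, _ = small_survey
        resp_only = relatives[relatives["roster_source"] == "respondent"].copy()
        est = {"n": lambda resp, rel: float(len(rel))}
        out = spouse_exclusion(respondents, resp_only, est)
        assert (out["delta"] == 0).all()

    def test_fixture_spouse_removal_leaves_9093(self, paper_fixture):
        est = {"n": lambda resp, rel: float(len(rel))}
        out = spouse_exclusion(paper_fixture["respondents"], paper_fixture["relatives"], est)
        assert out.loc[0, "full"] == 10725
        assert out.loc[0, "spouse_excluded"] == 9093

    def test_shared_generating_process_gives_small_deltas(self, small_resolved):
        """Spouse rosters are drawn from the same hazards, so excluding
        them shifts the rate by less than its sampling noise."""
        respondents, resolved = small_resolved
        sibs = resolved[resolved["relation"] == "sibling"]
        full = rate_from_resolved(sibs, WAR, (15, 50))
        excl = rate_from_resolved(sibs[sibs["roster_source"] == "respondent"], WAR, (15, 50))
        se = 1000 * np.sqrt(max(full.deaths, 1)) / full.person_years
        assert abs(excl.rate_per_1000py - full.rate_per_1000py) < 4 * se

    def test_respondent_only_tabulations_unchanged(self, paper_fixture):
        rel = paper_fixture["relatives"]
        resp_only = rel[rel["roster_source"] == "respondent"]
        a = assemble_rosters(paper_fixture["respondents"], resp_only).table
        both = assemble_rosters(paper_fixture["respondents"], rel).table
        b = both[both["roster_source"] == "respondent"]
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )


def _war_rate(resolved):
    return rate_from_resolved(resolved[resolved["relation"] == "sibling"], WAR, (15, 50)).rate_per_1000py


class TestMigrationSensitivity:
    def test_zero_departure_reproduces_primary_analysis(self, small_resolved):
        _, resolved = small_resolved
        sims = migration_sensitivity(resolved, MigrationScenario(0.0, 5, seed=1), _war_rate)
        primary = _war_rate(resolved)
        assert (sims["estimate"] == primary).all()

    def test_full_departure_weakly_increases_war_rate(self, small_resolved):
        _, resolved = small_resolved
        primary = _war_rate(resolved)
        sims = migration_sensitivity(resolved, MigrationScenario(1.0, 3, seed=2), _war_rate)
        assert (sims["estimate"] >= primary - 1e-9).all()

    def test_fixed_seed_reproducible(self, small_resolved):
        _, resolved = small_resolved
        sc = MigrationScenario(0.2, 4, seed=9)
        a = migration_sensitivity(resolved, sc, _war_rate)
        b = migration_sensitivity(resolved, sc, _war_rate)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_proportion_rejected(self, small_resolved):
        _, resolved = small_resolved
        with pytest.raises(ValueError, match="departure_proportion"):
            migration_sensitivity(resolved, MigrationScenario(1.5, 2), _war_rate)

    def test_no_eligible_individuals_rejected(self, small_resolved):
        _, resolved = small_resolved
        dead_only = resolved[resolved["status"] == "deceased"]
        with pytest.raises(ValueError, match="eligible"):
            migration_sensitivity(dead_only, MigrationScenario(0.5, 2, seed=0), _war_rate)

    def test_median_shift_matches_expected_denominator_calculation(self, small_resolved):
        """At departure proportion p the expected war-period person-time of
        each alive individual can be written in closed form (uniform
        departure date); the simulated median rate must match the rate
        implied by that expected denominator within 2%."""
        _, resolved = small_resolved
        p = 0.1
        sibs = resolved[resolved["relation"] == "sibling"].reset_index(drop=True)
        from kinrates.exposure import AgeStratum, cell_exposure

        py, dth = cell_exposure(sibs, WAR, AgeStratum(180, 600))
        deaths = dth.sum()
        alive = ((sibs["status"] == "alive") & sibs["include"]).to_numpy()

        # closed-form expected censored exposure per alive individual:
        # departure D ~ U[w0, end_i); war-cell exposure interval [a_i, b_i)
        w0 = date_to_day(WAR.start)
        end = pd.DatetimeIndex(sibs["end"]).values.astype("datetime64[D]").astype("int64")
        birth = pd.DatetimeIndex(sibs["birth"]).values.astype("datetime64[D]").astype("int64")
        from kinrates.dates import shift_months

        entry = pd.DatetimeIndex(shift_months(sibs["birth"], 180)).values.astype("datetime64[D]").astype("int64")
        exit_ = pd.DatetimeIndex(shift_months(sibs["birth"], 600)).values.astype("datetime64[D]").astype("int64")
        a = np.maximum(entry, w0)
        b = np.minimum(np.minimum(exit_, date_to_day(WAR.end)), end)
        lo, hi = w0, np.maximum(end, w0 + 1)
        # E[ clip(min(D, b) - a, 0) ] for D uniform on [lo, hi)
        exp_c = np.zeros(len(sibs))
        for i in range(len(sibs)):
            if b[i] <= a[i]:
                continue
            d = np.arange(lo, hi[i])
            exp_c[i] = np.clip(np.minimum(d, b[i]) - a[i], 0, None).mean() / 365.25
        expected_py = np.where(alive, (1 - p) * py + p * exp_c, py).sum()
        expected_rate = 1000.0 * deaths / expected_py

        sims = migration_sensitivity(
            sibs, MigrationScenario(p, 60, seed=3), lambda r: _war_rate(r.assign(relation="sibling"))
        )
        med = summarise_migration(sims)["median"]
        assert abs(med - expected_rate) / expected_rate < 0.02


class TestExcessDeaths:
    def _frame(self):
        return PopulationFrame(
            population=1_000_000, shares={"15-49": 0.8, "60-99": 0.2}, period_years=2.0
        )

    def _rates(self, war=(20.0, 50.0), base=(1.0, 20.0)):
        return pd.DataFrame(
            {"band": ["15-49", "60-99"], "rate_war": war, "rate_baseline": base}
        )

    def test_equal_rates_zero_excess(self):
        out = excess_deaths(self._rates(war=(1.0, 20.0)), self._frame())
        assert out["excess_deaths"] == pytest.approx(0.0)

    def test_single_band_hand_product(self):
        frame = PopulationFrame(1_000_000, {"15-49": 1.0}, 2.0)
        rates = pd.DataFrame({"band": ["15-49"], "rate_war": [21.0], "rate_baseline": [1.0]})
        out = excess_deaths(rates, frame)
        assert out["excess_deaths"] == pytest.approx(40_000.0)

    def test_linear_in_population_and_period(self):
        base = excess_deaths(self._rates(), self._frame())["excess_deaths"]
        f2 = self._frame()
        f2.population *= 3
        assert excess_deaths(self._rates(), f2)["excess_deaths"] == pytest.approx(3 * base)
        f3 = self._frame()
        f3.period_years *= 0.5
        assert excess_deaths(self._rates(), f3)["excess_deaths"] == pytest.approx(base / 2)

    def test_missing_band_rejected(self):
        with pytest.raises(ValueError, match="60-99"):
            excess_deaths(self._rates().iloc[:1], self._frame())

    def test_ci_propagates_replicates(self):
        rng = np.random.default_rng(0)
        reps = {
            "15-49": (rng.normal(20, 1, 200), rng.normal(1, 0.2, 200)),
            "60-99": (rng.normal(50, 2, 200), rng.normal(20, 1, 200)),
        }
        out = excess_deaths(self._rates(), self._frame(), replicates=reps)
        assert out["ci_lo"] < out["excess_deaths"] < out["ci_hi"]
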