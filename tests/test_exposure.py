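"""Exposure engine: date resolution rules, interval arithmetic, invariants."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kinrates.exposure import (
    AgeStratum,
    Period,
    accumulate,
    cell_exposure,
    day_step_exposure,
    resolve_dates,
)

COMPLETION = pd.Series([pd.Timestamp("2023-01-15")], index=["R1"])


def _rel(**kw):
    base = dict(
        respondent_id="R1", sex="male", status="alive",
        birth_year=np.nan, birth_month=np.nan, age_at_survey=np.nan,
        death_year=np.nan, death_month=np.nan, age_at_death=np.nan,
    )
    base.update(kw)
    return pd.DataFrame([base])


class TestResolveDates:
    def test_alive_age_only_uses_mid_interval_birth(self):
        res = resolve_dates(_rel(age_at_survey=30), COMPLETION)
        assert res["birth"].iloc[0] == pd.Timestamp("1992-07-15")
        assert res["end"].iloc[0] == pd.Timestamp("2023-01-15")
        assert not res["died"].iloc[0]

    def test_year_only_war_death_clamps_collection_midpoint_into_year(self):
        # collection window 2022-11-06..2023-04-18 has its midpoint in
        # January 2023; a death fixed to 2022 must clamp to December 2022
        res = resolve_dates(_rel(status="deceased", death_year=2022, age_at_death=40), COMPLETION)
        assert res["death_date"].iloc[0] == pd.Timestamp("2022-12-15")

    def test_year_only_prewar_death_takes_mid_year(self):
        res = resolve_dates(_rel(status="deceased", death_year=2012, age_at_death=40), COMPLETION)
        assert res["death_date"].iloc[0] == pd.Timestamp("2012-07-15")

    def test_full_dates_give_day_count_lifespan(self):
        res = resolve_dates(
            _rel(status="deceased", birth_year=2010, birth_month=1, death_year=2015, death_month=3),
            COMPLETION,
        )
        days = (res["end"].iloc[0] - res["birth"].iloc[0]).days
        assert days == 1885
        assert res["died"].iloc[0]

    def test_unknown_status_excluded_by_default_included_as_alive_on_request(self):
        rel = _rel(status="unknown", age_at_survey=50)
        res = resolve_dates(rel, COMPLETION)
        assert not res["include"].iloc[0]
        assert res["exclusion_reason"].iloc[0] == "status_unknown"
        res2 = resolve_dates(rel, COMPLETION, unknown_as_alive=True)
        assert res2["include"].iloc[0]
        assert not res2["died"].iloc[0]

    def test_death_before_birth_excluded_with_reason(self):
        res = resolve_dates(
            _rel(status="deceased", birth_year=2015, birth_month=6, death_year=2010, death_month=1),
            COMPLETION,
        )
        assert not res["include"].iloc[0]
        assert res["exclusion_reason"].iloc[0] == "death_before_birth"

    def test_inconsistent_age_at_death_excluded(self):
        res = resolve_dates(
            _rel(status="deceased", birth_year=1980, birth_month=1,
                 death_year=2020, death_month=1, age_at_death=20),
            COMPLETION,
        )
        assert not res["include"].iloc[0]
        assert res["exclusion_reason"].iloc[0] == "age_at_death_inconsistent"

    def test_unknown_respondent_rejected(self):
        with pytest.raises(ValueError, match="unknown respondents"):
            resolve_dates(_rel(respondent_id="nope", age_at_survey=10), COMPLETION)


def _resolved_row(birth, end, death=None, sex="male"):
    return pd.DataFrame(
        {
            "birth": [pd.Timestamp(birth)],
            "end": [pd.Timestamp(end)],
            "death_date": [pd.Timestamp(death) if death else pd.NaT],
            "died": [death is not None],
            "include": [True],
            "sex": [sex],
        }
    )


class TestCellExposure:
    def test_worked_example_partial_overlap(self):
        # born 2000-01-15, ages 20-24 intersected with the conflict window
        row = _resolved_row("2000-01-15", "2023-04-18")
        p = Period("w", dt.date(2020, 11, 4), dt.date(2023, 4, 18))
        py, d = cell_exposure(row, p, AgeStratum(240, 300))
        assert py[0] == pytest.approx(895 / 365.25, abs=1e-12)
        assert d[0] == 0

    def test_death_before_period_contributes_nothing(self):
        row = _resolved_row("2000-01-15", "2004-03-15", death="2004-03-15")
        p = Period("p", dt.date(2010, 1, 1), dt.date(2015, 1, 1))
        py, d = cell_exposure(row, p, AgeStratum(0, 1200))
        assert py[0] == 0.0 and d[0] == 0

    def test_death_on_period_boundary_belongs_to_later_period(self):
        row = _resolved_row("2000-01-15", "2015-01-01", death="2015-01-01")
        early = Period("a", dt.date(2010, 1, 1), dt.date(2015, 1, 1))
        late = Period("b", dt.date(2015, 1, 1), dt.date(2020, 1, 1))
        s = AgeStratum(0, 1200)
        _, d_early = cell_exposure(row, early, s)
        _, d_late = cell_exposure(row, late, s)
        assert d_early[0] == 0 and d_late[0] == 1

    def test_stratum_split_conserves_total(self):
        # one person crossing an age boundary mid-period
        row = _resolved_row("2000-06-15", "2023-01-15")
        p = Period("p", dt.date(2015, 1, 1), dt.date(2020, 1, 1))
        full, _ = cell_exposure(row, p, AgeStratum(0, 1200))
        a, _ = cell_exposure(row, p, AgeStratum(0, 180))
        b, _ = cell_exposure(row, p, AgeStratum(180, 1200))
        assert a[0] + b[0] == pytest.approx(full[0], abs=1e-9)

    def test_widening_period_never_shrinks_exposure(self):
        row = _resolved_row("2000-06-15", "2023-01-15")
        narrow = Period("n", dt.date(2016, 1, 1), dt.date(2018, 1, 1))
        wide = Period("w", dt.date(2015, 1, 1), dt.date(2020, 1, 1))
        s = AgeStratum(120, 300)
        assert cell_exposure(row, wide, s)[0][0] >= cell_exposure(row, narrow, s)[0][0]


class TestAccumulate:
    def test_overlapping_periods_rejected(self):
        row = _resolved_row("2000-01-15", "2023-01-15")
        ps = [Period("a", dt.date(2010, 1, 1), dt.date(2016, 1, 1)),
              Period("b", dt.date(2015, 1, 1), dt.date(2020, 1, 1))]
        with pytest.raises(ValueError, match="overlapping"):
            accumulate(row, ps, [AgeStratum(0, 1200)])

    def test_every_death_lands_in_exactly_one_cell(self, small_resolved):
        _, resolved = small_resolved
        ps = [Period("a", dt.date(1920, 1, 1), dt.date(2000, 1, 1)),
              Period("b", dt.date(2000, 1, 1), dt.date(2024, 1, 1))]
        strata = [AgeStratum(0, 600), AgeStratum(600, 1200)]
        led = accumulate(resolved, ps, strata, by_sex=True)
        in_scope = resolved[resolved["include"] & resolved["died"]]
        assert led["deaths"].sum() == len(in_scope)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        birth_m=st.integers(0, 600),
        life_m=st.integers(1, 600),
        died=st.booleans(),
    )
    def test_conservation_over_partition(self, birth_m, life_m, died):
        """Summed exposure over a partition of cells equals the overlap of
        the lifespan with the analysis window, to under a day."""
        birth = pd.Timestamp("1970-01-15") + pd.DateOffset(months=birth_m)
        end = birth + pd.DateOffset(months=life_m)
        row = _resolved_row(birth, end, death=end if died else None)
        window = (dt.date(1990, 1, 1), dt.date(2020, 1, 1))
        ps = [Period("a", window[0], dt.date(2005, 1, 1)),
              Period("b", dt.date(2005, 1, 1), window[1])]
        strata = [AgeStratum(0, 120), AgeStratum(120, 360), AgeStratum(360, 1200)]
        led = accumulate(row, ps, strata)
        lo = max(pd.Timestamp(window[0]), birth)
        hi = min(pd.Timestamp(window[1]), end)
        expected = max((hi - lo).days, 0) / 365.25
        assert led["person_years"].sum() == pytest.approx(expected, abs=1.01 / 365.25)


class TestOracleAgreement:
    def test_closed_form_matches_day_stepping_on_random_lifespans(self):
        rng = np.random.default_rng(1234)
        n = 120
        # birth days capped at 28: month arithmetic clamps later days, and
        # the resolver only ever emits day-15 births
        months = rng.integers(0, 600, n)
        births = pd.Timestamp("1960-01-01") + pd.Series(
            [pd.DateOffset(months=int(m), days=int(d)) for m, d in zip(months, rng.integers(0, 28, n))]
        )
        spans = rng.integers(30, 55 * 365, n)
        died = rng.random(n) < 0.5
        ends = births + pd.to_timedelta(spans, "D")
        rows = pd.DataFrame(
            {
                "birth": births,
                "end": ends,
                "death_date": np.where(died, ends, pd.NaT),
                "died": died,
                "include": True,
                "sex": "male",
            }
        )
        p = Period("p", dt.date(1990, 1, 1), dt.date(2015, 6, 1))
        s = AgeStratum(int(rng.integers(0, 300)), int(rng.integers(301, 900)))
        py, d = cell_exposure(rows, p, s)
        for i in range(n):
            o_py, o_d = day_step_exposure(rows.iloc[i], p, s)
            assert abs(py[i] - o_py) < 1.0 / 365.25
            assert d[i] == o_d
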