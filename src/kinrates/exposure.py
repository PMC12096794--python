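"""Person-time exposure engine.

Computes, for every reported relative, the exact time at risk contributed to
arbitrary period x age-stratum x sex cells, and assigns each death to the
unique cell containing its date. This is the denominator machinery shared by
the child-mortality, adult-rate and fertility estimators.

Conventions
-----------
* Half-open intervals everywhere: periods ``[start, end)``, age strata
  ``[lo, hi)`` in months. A death falling exactly on a period boundary
  belongs to the later period.
* Dates are month-resolved with day 15, except the conflict onset
  (4 November 2020) and per-respondent completion dates.
* Person-years = day count / 365.25.
* Alive relatives are censored at their respondent's completion date.
  Status-unknown relatives contribute neither deaths nor person-time by
  default (``unknown_as_alive=True`` treats them as alive-censored, for
  sensitivity analysis).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from kinrates.dates import (
    DAYS_PER_YEAR,
    MID_DAY,
    as_day_array,
    date_to_day,
    shift_months,
)

# Fixed day-level anchors of the survey design.
WAR_START = dt.date(2020, 11, 4)
COLLECTION_START = dt.date(2022, 11, 6)
COLLECTION_END = dt.date(2023, 4, 18)
ANALYSIS_END = dt.date(2023, 4, 19)  # exclusive


@dataclass(frozen=True)
class Period:
    """A calendar period ``[start, end)``."""

    label: str
    start: dt.date
    end: dt.date

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"period {self.label!r}: start {self.start} >= end {self.end}")

    @property
    def years(self) -> float:
        return (date_to_day(self.end) - date_to_day(self.start)) / DAYS_PER_YEAR

    def contains(self, d: dt.date) -> bool:
        return self.start <= d < self.end


@dataclass(frozen=True)
class AgeStratum:
    """An age band ``[lo, hi)`` in completed months."""

    lo: int
    hi: int

    def __post_init__(self):
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"invalid age stratum [{self.lo}, {self.hi})")

    @property
    def width_years(self) -> float:
        return (self.hi - self.lo) / 12.0

    @property
    def label(self) -> str:
        if self.lo % 12 == 0 and self.hi % 12 == 0:
            return f"{self.lo // 12}-{self.hi // 12 - 1}y"
        return f"{self.lo}-{self.hi - 1}m"


def standard_periods() -> list[Period]:
    """The four analysis periods for children, young cohorts and adults."""
    return [
        Period("2005-2009", dt.date(2005, 1, 1), dt.date(2010, 1, 1)),
        Period("2010-2014", dt.date(2010, 1, 1), dt.date(2015, 1, 1)),
        Period("2015-2020", dt.date(2015, 1, 1), WAR_START),
        Period("war", WAR_START, ANALYSIS_END),
    ]


def older_adult_periods() -> list[Period]:
    """Decade pre-war periods plus the war period, for older-adult rates."""
    return [
        Period("1980-1989", dt.date(1980, 1, 1), dt.date(1990, 1, 1)),
        Period("1990-1999", dt.date(1990, 1, 1), dt.date(2000, 1, 1)),
        Period("2000-2009", dt.date(2000, 1, 1), dt.date(2010, 1, 1)),
        Period("2010-2020", dt.date(2010, 1, 1), WAR_START),
        Period("war", WAR_START, ANALYSIS_END),
    ]


def five_year_strata(lo_years: int = 15, hi_years: int = 50) -> list[AgeStratum]:
    return [AgeStratum(a * 12, (a + 5) * 12) for a in range(lo_years, hi_years, 5)]


U5_STRATA = [AgeStratum(0, 12), AgeStratum(12, 60)]
CHILD_5_14_STRATA = [AgeStratum(60, 120), AgeStratum(120, 180)]
YOUTH_15_24_STRATA = [AgeStratum(180, 240), AgeStratum(240, 300)]
OLDER_ADULT_STRATUM = AgeStratum(60 * 12, 100 * 12)  # 60-99 years


def _collection_midpoint(start: dt.date, end: dt.date) -> dt.date:
    return start + dt.timedelta(days=(end - start).days // 2)


def _clamped_mid_month(year: int, mid: dt.date) -> int:
    """Month for a year-only death in a collection-window year: the window
    midpoint month, clamped into the stated death year."""
    if year < mid.year:
        return 12
    if year > mid.year:
        return 1
    return mid.month


def resolve_dates(
    relatives: pd.DataFrame,
    completion: pd.Series,
    *,
    collection_start: dt.date = COLLECTION_START,
    collection_end: dt.date = COLLECTION_END,
    war_start: dt.date = WAR_START,
    unknown_as_alive: bool = False,
) -> pd.DataFrame:
    """Resolve each relative's roster fields into a lifespan.

    Parameters
    ----------
    relatives
        One row per relative with columns ``respondent_id, sex, status,
        birth_year, birth_month, age_at_survey, death_year, death_month,
        age_at_death`` (extra columns pass through).
    completion
        Respondent id -> survey completion date (datetime-like).

    Returns
    -------
    DataFrame with ``birth``, ``end`` (censor or death date, exclusive),
    ``death_date``, ``died``, ``include`` and ``exclusion_reason`` columns.
    Rules: alive -> censored at completion; births at day 15 of the stated
    month, or back-computed mid-interval (age + 6 months) from a stated age;
    year-only deaths in collection-window years take the collection-window
    midpoint month clamped into the year, earlier year-only deaths take
    July; age-only deaths are placed mid-interval after the birth date.
    Irreconcilable records (death before birth, age at death off by more
    than a year) are excluded with a reason.
    """
    df = relatives.reset_index(drop=True).copy()
    n = len(df)
    comp = pd.to_datetime(df["respondent_id"].map(completion))
    if comp.isna().any():
        bad = df.loc[comp.isna(), "respondent_id"].unique()[:5]
        raise ValueError(f"relatives reference unknown respondents, e.g. {list(bad)}")

    status = df["status"].astype(str)
    alive_like = (status == "alive") | (unknown_as_alive & (status == "unknown"))
    deceased = status == "deceased"

    by = pd.to_numeric(df.get("birth_year"), errors="coerce")
    bm = pd.to_numeric(df.get("birth_month"), errors="coerce")
    aas = pd.to_numeric(df.get("age_at_survey"), errors="coerce")
    dy = pd.to_numeric(df.get("death_year"), errors="coerce")
    dm = pd.to_numeric(df.get("death_month"), errors="coerce")
    aad = pd.to_numeric(df.get("age_at_death"), errors="coerce")

    reason = np.full(n, "", dtype=object)
    mid = _collection_midpoint(collection_start, collection_end)

    # --- death dates ---
    death = pd.Series(pd.NaT, index=df.index, dtype="datetime64[ns]")
    m_full = deceased & dy.notna() & dm.notna()
    if m_full.any():
        death.loc[m_full] = pd.to_datetime(
            {"year": dy[m_full].astype(int), "month": dm[m_full].astype(int), "day": MID_DAY}
        ).values
    m_yronly = deceased & dy.notna() & dm.isna()
    if m_yronly.any():
        yrs = dy[m_yronly].astype(int)
        months = np.where(
            yrs >= war_start.year,
            [_clamped_mid_month(y, mid) for y in yrs],
            7,
        )
        death.loc[m_yronly] = pd.to_datetime(
            {"year": yrs, "month": months, "day": MID_DAY}
        ).values

    # --- birth dates ---
    birth = pd.Series(pd.NaT, index=df.index, dtype="datetime64[ns]")
    m_bym = by.notna() & bm.notna()
    if m_bym.any():
        birth.loc[m_bym] = pd.to_datetime(
            {"year": by[m_bym].astype(int), "month": bm[m_bym].astype(int), "day": MID_DAY}
        ).values
    # alive (or unknown-as-alive) with an age only: mid-interval back-computation
    m_age = birth.isna() & alive_like & aas.notna()
    if m_age.any():
        birth.loc[m_age] = shift_months(
            comp[m_age], -(aas[m_age].astype(int) * 12 + 6), day=MID_DAY
        ).values
    # deceased with age at death and a resolvable death date
    m_back = birth.isna() & deceased & aad.notna() & death.notna()
    if m_back.any():
        birth.loc[m_back] = shift_months(
            death[m_back], -(aad[m_back].astype(int) * 12 + 6), day=MID_DAY
        ).values
    # deceased with birth and age at death but no death year: mid-interval forward
    m_fwd = death.isna() & deceased & aad.notna() & birth.notna()
    if m_fwd.any():
        death.loc[m_fwd] = shift_months(
            birth[m_fwd], aad[m_fwd].astype(int) * 12 + 6, day=MID_DAY
        ).values

    include = np.ones(n, dtype=bool)

    unknown = (status == "unknown") & ~alive_like
    include[unknown] = False
    reason[unknown] = "status_unknown"

    no_birth = birth.isna() & include
    reason[no_birth & alive_like] = "no_birth_info"
    reason[no_birth & deceased] = "no_birth_info"
    include[no_birth.values] = False

    no_death = deceased & death.isna() & include
    reason[no_death] = "unresolvable_death_date"
    include[no_death.values] = False

    # consistency: stated age at death vs implied age
    chk = deceased & include & aad.notna() & birth.notna() & death.notna() & dy.notna() & m_bym
    if chk.any():
        implied = (death[chk] - birth[chk]).dt.days / DAYS_PER_YEAR
        off = (implied - aad[chk]).abs() > 1.5  # mid-interval placement allows +-0.5
        bad = chk.index[chk][off]
        include[bad] = False
        reason[bad] = "age_at_death_inconsistent"

    neg = include & death.notna() & birth.notna() & (death < birth)
    include[neg.values] = False
    reason[neg.values] = "death_before_birth"

    out = df.copy()
    out["birth"] = birth
    out["death_date"] = death.where(deceased)
    out["died"] = deceased & include
    out["end"] = np.where(deceased, death.values, comp.values)
    out["end"] = pd.to_datetime(out["end"])
    out["include"] = include
    out["exclusion_reason"] = reason
    return out


def cell_exposure(
    resolved: pd.DataFrame, period: Period, stratum: AgeStratum
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual person-years and death indicator for one cell.

    Exposure is the day-count length of
    ``[birth + lo months, birth + hi months) ∩ [period.start, period.end)
    ∩ [birth, end)`` divided by 365.25; the death indicator marks rows whose
    death date lies in the cell. Rows flagged ``include == False`` get zero.
    """
    b = resolved["birth"]
    entry = as_day_array(shift_months(b, stratum.lo))
    exit_ = as_day_array(shift_months(b, stratum.hi))
    e = as_day_array(resolved["end"])
    p0, p1 = date_to_day(period.start), date_to_day(period.end)

    start = np.maximum(entry, p0)
    stop = np.minimum(np.minimum(exit_, p1), e)
    days = np.clip(stop - start, 0, None)
    py = days / DAYS_PER_YEAR

    dd = resolved["death_date"]
    ddy = as_day_array(dd)
    has = dd.notna().to_numpy()
    died = resolved["died"].to_numpy(dtype=bool) & has
    in_cell = died & (ddy >= start) & (ddy < np.minimum(exit_, p1)) & (ddy >= entry) & (ddy >= p0)

    inc = resolved["include"].to_numpy(dtype=bool)
    py = np.where(inc, py, 0.0)
    in_cell = in_cell & inc
    return py, in_cell


def _check_disjoint(periods: list[Period]) -> None:
    ps = sorted(periods, key=lambda p: p.start)
    for a, b in zip(ps, ps[1:]):
        if a.end > b.start:
            raise ValueError(f"overlapping periods: {a.label!r} and {b.label!r}")


def accumulate(
    resolved: pd.DataFrame,
    periods: list[Period],
    strata: list[AgeStratum],
    by_sex: bool = True,
) -> pd.DataFrame:
    """Build a person-time ledger: one row per period x stratum x sex cell.

    Returns a tidy DataFrame with columns ``period, age_lo_m, age_hi_m, sex,
    person_years, deaths``. Periods must be disjoint. With ``by_sex=False``
    a single ``all`` sex level aggregates everyone (including sex-unknown,
    which is otherwise reported as its own level).
    """
    _check_disjoint(periods)
    sex = resolved["sex"].astype(str).to_numpy()
    levels = ["male", "female", "unknown"] if by_sex else ["all"]
    rows = []
    for p in periods:
        for s in strata:
            py, dth = cell_exposure(resolved, p, s)
            for lv in levels:
                m = np.ones(len(py), dtype=bool) if lv == "all" else sex == lv
                rows.append(
                    {
                        "period": p.label,
                        "age_lo_m": s.lo,
                        "age_hi_m": s.hi,
                        "sex": lv,
                        "person_years": float(py[m].sum()),
                        "deaths": int(dth[m].sum()),
                    }
                )
    return pd.DataFrame(rows)


def day_step_exposure(
    resolved_row: pd.Series, period: Period, stratum: AgeStratum
) -> tuple[float, int]:
    """Slow day-stepping reference for :func:`cell_exposure` (validation only).

    Walks every calendar day of the lifespan, recomputes completed-months
    age from calendar fields, and counts days falling in the cell. Shares
    no interval arithmetic with the closed form.
    """
    b = pd.Timestamp(resolved_row["birth"])
    e = pd.Timestamp(resolved_row["end"])
    p0 = pd.Timestamp(period.start)
    p1 = pd.Timestamp(period.end)
    lo_day = max(b, p0)
    hi_day = min(e, p1)
    days = 0
    if hi_day > lo_day:
        rng = pd.date_range(lo_day, hi_day - pd.Timedelta(days=1), freq="D")
        age_m = (rng.year - b.year) * 12 + (rng.month - b.month) - (rng.day < b.day)
        days = int(((age_m >= stratum.lo) & (age_m < stratum.hi)).sum())
    death = 0
    if bool(resolved_row["died"]) and pd.notna(resolved_row["death_date"]):
        d = pd.Timestamp(resolved_row["death_date"])
        if p0 <= d < p1:
            age_m = (d.year - b.year) * 12 + (d.month - b.month) - (d.day < b.day)
            if stratum.lo <= age_m < stratum.hi:
                death = 1
    return days / DAYS_PER_YEAR, death
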