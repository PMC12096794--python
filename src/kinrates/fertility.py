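"""Fertility diagnostics: ASFR, TFR and birth intervals.

Age-specific fertility rates use births to linked siblings as the
numerator and sibling person-years from the exposure engine as the
denominator, in 5-year bands from 15 to 49. The total fertility rate is
exactly five times the sum of band ASFRs. These serve as validity checks
on roster completeness rather than as primary estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kinrates.exposure import Period, cell_exposure, five_year_strata


@dataclass
class FertilityResult:
    period: str
    reporter_sex: str
    table: pd.DataFrame  # band, births, person_years, asfr_per_1000
    n_unlinked: int = 0

    @property
    def tfr_value(self) -> float:
        return tfr(self.table)


def _age_months_at(birth: pd.Series, at: pd.Series) -> np.ndarray:
    b = pd.DatetimeIndex(birth)
    a = pd.DatetimeIndex(at)
    return ((a.year - b.year) * 12 + (a.month - b.month) - (a.day < b.day)).to_numpy()


def asfr(
    resolved: pd.DataFrame,
    period: Period,
    reporter_sex: str = "female",
) -> FertilityResult:
    """Age-specific fertility rates for siblings of the given sex.

    ``resolved`` is the full resolved roster: siblings of ``reporter_sex``
    provide person-time; nieces/nephews with a ``linked_sibling_id``
    pointing at one of those siblings provide births (dated by their own
    birth). Births without a resolvable linkage are excluded and counted.
    """
    sibs = resolved[(resolved["relation"] == "sibling") & (resolved["sex"] == reporter_sex)]
    kids = resolved[resolved["relation"] == "niece_nephew"].copy()
    link = kids["linked_sibling_id"].fillna("").astype(str)
    n_unlinked = int((link == "").sum())
    kids = kids[(link != "") & kids["birth"].notna()]

    sib_birth = sibs.set_index("relative_id")["birth"]
    kb = pd.to_datetime(kids["birth"])
    parent_birth = kids["linked_sibling_id"].map(sib_birth)
    m = parent_birth.notna()  # linked to a sibling of this sex
    kids, kb, parent_birth = kids[m], kb[m], pd.to_datetime(parent_birth[m])
    in_period = (kb >= pd.Timestamp(period.start)) & (kb < pd.Timestamp(period.end))
    kids, kb, parent_birth = kids[in_period], kb[in_period], parent_birth[in_period]
    age_m = _age_months_at(parent_birth, kb) if len(kids) else np.empty(0)

    rows = []
    for s in five_year_strata(15, 50):
        py, _ = cell_exposure(sibs, period, s)
        births = int(((age_m >= s.lo) & (age_m < s.hi)).sum())
        p = float(py.sum())
        rows.append(
            {
                "age_lo_y": s.lo // 12,
                "age_hi_y": s.hi // 12,
                "births": births,
                "person_years": p,
                "asfr_per_1000": 1000.0 * births / p if p > 0 else 0.0,
            }
        )
    return FertilityResult(
        period=period.label,
        reporter_sex=reporter_sex,
        table=pd.DataFrame(rows),
        n_unlinked=n_unlinked,
    )


def tfr(asfr_table: pd.DataFrame) -> float:
    """Total fertility rate: 5 x sum of band ASFRs (births per person).

    Requires all seven 5-year bands from 15 to 49.
    """
    expected = {(a, a + 5) for a in range(15, 50, 5)}
    got = set(zip(asfr_table["age_lo_y"], asfr_table["age_hi_y"]))
    missing = expected - got
    if missing:
        raise ValueError(f"asfr table missing bands: {sorted(missing)}")
    return float(5.0 * asfr_table["asfr_per_1000"].sum() / 1000.0)


@dataclass
class BirthIntervals:
    intervals_months: np.ndarray
    n_multiples: int = 0
    by_period: pd.DataFrame = field(default_factory=pd.DataFrame)


def birth_intervals(
    resolved: pd.DataFrame, periods: list[Period] | None = None
) -> BirthIntervals:
    """Distribution of intervals between consecutive births of one parent.

    First-borns contribute no interval; an interval belongs to the period
    of the later birth. Same-month births to one parent are treated as
    multiples: counted separately, excluded from the distribution.
    """
    kids = resolved[resolved["relation"] == "niece_nephew"].copy()
    link = kids["linked_sibling_id"].fillna("").astype(str)
    kids = kids[(link != "") & kids["birth"].notna()]
    if kids.empty:
        return BirthIntervals(np.empty(0, dtype=int), 0)
    kids = kids.sort_values(["linked_sibling_id", "birth"], kind="stable")
    b = pd.DatetimeIndex(kids["birth"])
    months = b.year * 12 + (b.month - 1)
    same = kids["linked_sibling_id"].to_numpy()
    prev_same = np.concatenate([[False], same[1:] == same[:-1]])
    gaps = np.diff(months.to_numpy(), prepend=months[0])
    iv = gaps[prev_same]
    later = b[prev_same]
    multiples = int((iv == 0).sum())
    keep = iv > 0
    iv, later = iv[keep], later[keep]

    by_period = pd.DataFrame()
    if periods:
        rows = []
        for p in periods:
            m = (later >= pd.Timestamp(p.start)) & (later < pd.Timestamp(p.end))
            rows.append(
                {
                    "period": p.label,
                    "n": int(m.sum()),
                    "mean_months": float(iv[m].mean()) if m.any() else np.nan,
                    "median_months": float(np.median(iv[m])) if m.any() else np.nan,
                }
            )
        by_period = pd.DataFrame(rows)
    return BirthIntervals(iv.astype(int), multiples, by_period)
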