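"""Survey ingest: eligibility/attrition accounting, roster validation and
death tabulations.

Eligibility is applied in a fixed order (age -> diaspora membership ->
duplicate family) so each access is counted once under the first failing
criterion; attrition then splits eligible accesses into non-consent,
consent-without-completion, and analysable. Percentages are reported to one
decimal, rounding half away from zero.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kinrates.exposure import AgeStratum, Period, resolve_dates

ZONE_LABELS = [
    "central",
    "eastern",
    "southern_southeastern",
    "north_western",
    "mekelle",
    "western",
    "unknown_zone",
]

_ELIGIBILITY_FIELDS = ["eligible_age", "diaspora_member", "duplicate_family", "consented", "completed"]


def completion_series(respondents: pd.DataFrame) -> pd.Series:
    """Respondent id -> completion date, for date resolution."""
    return pd.Series(
        pd.to_datetime(respondents["completion_date"]).values,
        index=respondents["respondent_id"].values,
    )


def round1(x: float) -> float:
    """One-decimal rounding, half away from zero."""
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


@dataclass
class AttritionReport:
    """Partition of survey accesses into eligibility and attrition buckets."""

    counts: dict
    table: pd.DataFrame
    malformed: pd.DataFrame

    @property
    def eligible(self) -> int:
        return self.counts["eligible"]

    @property
    def analysable(self) -> int:
        return self.counts["analysable"]


def apply_eligibility(accesses: pd.DataFrame) -> AttritionReport:
    """Partition raw survey accesses per the eligibility/attrition cascade.

    Buckets are disjoint and sum to the total: outside-age, non-diaspora,
    duplicate-family (in that order, first failing criterion counts), then
    among eligible: no-consent, consent-without-completion, analysable.
    Rows with missing eligibility fields are routed to a separate
    ``malformed`` frame, excluded from the partition.
    """
    df = accesses.copy()
    if len(df) == 0:
        counts = dict.fromkeys(
            ["all_accesses", "outside_age", "non_diaspora", "duplicate_family",
             "eligible", "no_consent", "incomplete", "analysable", "malformed"], 0)
        return AttritionReport(counts, _attrition_table(counts), df)

    bad = df[_ELIGIBILITY_FIELDS].isna().any(axis=1)
    malformed = df[bad]
    df = df[~bad]

    age_ok = df["eligible_age"].astype(bool)
    diaspora = df["diaspora_member"].astype(bool)
    dup = df["duplicate_family"].astype(bool)
    consent = df["consented"].astype(bool)
    comp = df["completed"].astype(bool)

    outside_age = ~age_ok
    non_diaspora = age_ok & ~diaspora
    duplicate = age_ok & diaspora & dup
    eligible = age_ok & diaspora & ~dup
    no_consent = eligible & ~consent
    incomplete = eligible & consent & ~comp
    analysable = eligible & consent & comp

    counts = {
        "all_accesses": int(len(accesses)),
        "outside_age": int(outside_age.sum()),
        "non_diaspora": int(non_diaspora.sum()),
        "duplicate_family": int(duplicate.sum()),
        "eligible": int(eligible.sum()),
        "no_consent": int(no_consent.sum()),
        "incomplete": int(incomplete.sum()),
        "analysable": int(analysable.sum()),
        "malformed": int(bad.sum()),
    }
    if "generation" in df.columns:
        gen = df.loc[analysable, "generation"].value_counts().to_dict()
        counts["by_generation"] = {int(k): int(v) for k, v in sorted(gen.items())}
    return AttritionReport(counts, _attrition_table(counts), malformed)


def _attrition_table(c: dict) -> pd.DataFrame:
    total = c["all_accesses"]
    elig = c["eligible"]
    rows = [
        ("all_accesses", c["all_accesses"], total),
        ("outside_age", c["outside_age"], total),
        ("non_diaspora", c["non_diaspora"], total),
        ("duplicate_family", c["duplicate_family"], total),
        ("eligible", c["eligible"], total),
        ("no_consent", c["no_consent"], elig),
        ("incomplete", c["incomplete"], elig),
        ("analysable", c["analysable"], elig),
    ]
    return pd.DataFrame(
        [
            {
                "group": g,
                "count": n,
                "denominator": d,
                "pct": round1(100.0 * n / d) if d else 0.0,
            }
            for g, n, d in rows
        ]
    )


@dataclass
class RosterSummary:
    table: pd.DataFrame  # relation x roster_source x status counts
    total: int
    flagged_no_date_no_age: pd.DataFrame = field(default_factory=pd.DataFrame)

    def status_totals(self) -> pd.Series:
        return self.table.groupby("status")["count"].sum()


def assemble_rosters(respondents: pd.DataFrame, relatives: pd.DataFrame) -> RosterSummary:
    """Validate referential integrity and tabulate relation x source x status.

    Raises on orphan relatives (unknown respondent ids) or on a
    niece/nephew linkage pointing outside the roster. Deceased records with
    neither a death date nor an age at death are flagged but retained.
    """
    known = set(respondents["respondent_id"])
    orphan = ~relatives["respondent_id"].isin(known)
    if orphan.any():
        ids = relatives.loc[orphan, "relative_id"].tolist()[:10]
        raise ValueError(f"orphan relatives (unknown respondent): {ids}")
    linked = relatives["linked_sibling_id"].fillna("").astype(str)
    has_link = linked != ""
    if has_link.any():
        bad = has_link & ~linked.isin(set(relatives["relative_id"]))
        if bad.any():
            ids = relatives.loc[bad, "relative_id"].tolist()[:10]
            raise ValueError(f"niece/nephew records with dangling sibling link: {ids}")

    dec = relatives["status"] == "deceased"
    no_date = relatives.get("death_year").isna() if "death_year" in relatives else True
    no_age = relatives.get("age_at_death").isna() if "age_at_death" in relatives else True
    flagged = relatives[dec & no_date & no_age]

    table = (
        relatives.groupby(["relation", "roster_source", "status"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return RosterSummary(table=table, total=len(relatives), flagged_no_date_no_age=flagged)


@dataclass
class DeathTabulation:
    total: int
    by_cause: pd.DataFrame
    by_sex: pd.DataFrame
    by_zone: pd.DataFrame
    by_age_band: pd.DataFrame
    location_split: pd.DataFrame  # all resolvable deaths: in Tigray / outside / unknown


def _pct_table(series: pd.Series, order=None) -> pd.DataFrame:
    counts = series.value_counts()
    if order is not None:
        counts = counts.reindex(order, fill_value=0)
    total = counts.sum()
    return pd.DataFrame(
        {
            "count": counts.astype(int),
            "pct": [round1(100.0 * c / total) if total else 0.0 for c in counts],
        }
    )


def tabulate_deaths(
    relatives: pd.DataFrame,
    completion: pd.Series | None = None,
    period: Period | None = None,
    scope: str = "in_tigray",
    age_range_years: tuple[int, int] | None = None,
    sex: str | None = None,
    cause: str | None = None,
    include_country_unknown: bool = False,
) -> DeathTabulation:
    """Cross-tabulate deaths by cause, sex, zone and age band.

    ``scope='in_tigray'`` keeps deaths located in a named zone or in an
    unknown zone within the region, and drops deaths outside the region;
    country-level-unknown locations are dropped too unless
    ``include_country_unknown``. ``period=None`` tabulates all deaths.
    ``relatives`` may be raw (then ``completion`` is required to resolve
    dates) or already resolved.
    """
    if "death_date" in relatives.columns and "include" in relatives.columns:
        resolved = relatives
    else:
        if completion is None:
            raise ValueError("completion dates required to resolve raw relative records")
        resolved = resolve_dates(relatives, completion)

    d = resolved[(resolved["status"] == "deceased") & resolved["death_date"].notna()].copy()

    loc = d["location_of_death"].fillna("").astype(str)
    in_tigray = loc.isin(ZONE_LABELS)
    split = pd.DataFrame(
        {
            "count": [
                int(in_tigray.sum()),
                int((loc == "outside_tigray").sum()),
                int((~in_tigray & (loc != "outside_tigray")).sum()),
            ]
        },
        index=["in_tigray", "outside_tigray", "unknown"],
    )
    tot = split["count"].sum()
    split["pct"] = [round1(100.0 * c / tot) if tot else 0.0 for c in split["count"]]

    if scope == "in_tigray":
        keep = in_tigray | (include_country_unknown & ~(loc == "outside_tigray"))
        d = d[keep]
    elif scope != "all":
        raise ValueError(f"unknown scope {scope!r}")

    if period is not None:
        dd = pd.to_datetime(d["death_date"])
        d = d[(dd >= pd.Timestamp(period.start)) & (dd < pd.Timestamp(period.end))]

    aad = pd.to_numeric(d["age_at_death"], errors="coerce")
    implied = (pd.to_datetime(d["death_date"]) - pd.to_datetime(d["birth"])).dt.days / 365.25
    age = aad.fillna(np.floor(implied))
    if age_range_years is not None:
        lo, hi = age_range_years
        d = d[(age >= lo) & (age < hi)]
        age = age[(age >= lo) & (age < hi)]
    if sex is not None:
        d = d[d["sex"] == sex]
        age = age[d.index.intersection(age.index)]
    if cause is not None:
        d = d[d["cause"] == cause]

    age = age.loc[d.index]
    bands = pd.cut(
        age, [0, 5, 15, 50, 60, 100], right=False,
        labels=["0-4", "5-14", "15-49", "50-59", "60-99"],
    )
    return DeathTabulation(
        total=len(d),
        by_cause=_pct_table(d["cause"]),
        by_sex=_pct_table(d["sex"]),
        by_zone=_pct_table(d["location_of_death"], order=ZONE_LABELS) if scope == "in_tigray" else _pct_table(d["location_of_death"]),
        by_age_band=_pct_table(bands),
        location_split=split,
    )


def filter_death_location_scope(
    resolved: pd.DataFrame, scope: str = "in_tigray", include_country_unknown: bool = False
) -> pd.DataFrame:
    """Primary-analysis record filter: drop individuals who died outside the
    region (and, by default, deaths with country-level-unknown location)."""
    if scope == "all":
        return resolved
    loc = resolved["location_of_death"].fillna("").astype(str)
    dec = resolved["status"] == "deceased"
    drop = dec & (loc == "outside_tigray")
    if not include_country_unknown:
        drop |= dec & ~loc.isin(ZONE_LABELS) & (loc != "outside_tigray")
    return resolved[~drop]
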