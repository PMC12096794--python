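"""Synthetic diaspora-survey generator and packaged tabulation fixture.

Generates family rosters (two parents, siblings, nieces/nephews linked to a
sibling) for each respondent — and, for a fraction of respondents, for a
spouse — with lifespans drawn from a piecewise-constant hazard schedule,
births from an age-specific fertility process, and survey-style reporting
noise (month-only death dates, age-only birth reporting, unknown-status
masking). Ground truth (the exact rates used, and each relative's true
status) is returned separately and never merged into the survey export.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from kinrates.config import ASSET_ITEMS, SimConfig
from kinrates.dates import DAYS_PER_YEAR, date_to_day
from kinrates.exposure import WAR_START

_DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0

_GENERATION_P = [0.884, 0.093, 0.018, 0.005]
_WAR_CAUSE_P = {"starvation_disease": 0.206, "other": 0.046, "unknown": 0.025}
_PREWAR_CAUSE_P = {"intentional_injury": 0.03, "starvation_disease": 0.40, "other": 0.47, "unknown": 0.10}


# ---------------------------------------------------------------------------
# lifespan simulation
# ---------------------------------------------------------------------------

def _compile_schedule(hs: pd.DataFrame):
    """Compile a tidy hazard schedule into lookup arrays.

    Returns (period_bounds_days, age_offsets_days, R) where R has shape
    (2, n_periods, n_ages) indexed by sex (0=male, 1=female).
    """
    starts = np.array(sorted({date_to_day(d) for d in hs["start"]}), dtype="int64")
    end = max(date_to_day(d) for d in hs["end"])
    pbounds = np.append(starts, end)
    abounds_m = np.array(sorted(set(hs["age_lo_m"])) + [int(hs["age_hi_m"].max())], dtype="int64")
    aoff = np.round(abounds_m * _DAYS_PER_MONTH).astype("int64")
    R = np.zeros((2, len(pbounds) - 1, len(abounds_m) - 1))
    sidx = {"male": 0, "female": 1}
    pidx = {d: i for i, d in enumerate(starts)}
    aidx = {a: i for i, a in enumerate(abounds_m[:-1])}
    for row in hs.itertuples(index=False):
        R[sidx[row.sex], pidx[date_to_day(row.start)], aidx[row.age_lo_m]] = row.rate
    return pbounds, aoff, R


def simulate_lifespans(
    birth_day: np.ndarray,
    sex_code: np.ndarray,
    horizon_day: np.ndarray,
    compiled,
    rng: np.random.Generator,
    mult: np.ndarray | None = None,
) -> np.ndarray:
    """Draw death days under piecewise-constant hazards by inversion.

    Each person's lifetime is partitioned into segments on which the hazard
    is constant (changes at calendar period boundaries and at the person's
    own age-band boundaries); a unit-exponential draw is inverted against
    the cumulative hazard. Returns float days since epoch, NaN = alive at
    the horizon.
    """
    pbounds, aoff, R = compiled
    n = len(birth_day)
    if n == 0:
        return np.empty(0)
    birth_day = np.asarray(birth_day, dtype="int64")
    horizon_day = np.asarray(horizon_day, dtype="int64")
    cand = np.concatenate(
        [np.broadcast_to(pbounds, (n, len(pbounds))), birth_day[:, None] + aoff[None, :]],
        axis=1,
    ).astype("float64")
    cand = np.clip(cand, birth_day[:, None], horizon_day[:, None])
    cand.sort(axis=1)
    seg_len = np.diff(cand, axis=1)  # days
    mid = (cand[:, :-1] + cand[:, 1:]) / 2.0
    pi = np.clip(np.searchsorted(pbounds, mid, side="right") - 1, 0, R.shape[1] - 1)
    ai = np.clip(
        np.searchsorted(aoff, mid - birth_day[:, None], side="right") - 1, 0, R.shape[2] - 1
    )
    rate = R[np.asarray(sex_code)[:, None], pi, ai]
    if mult is not None:
        rate = rate * np.asarray(mult)[:, None]
    dh = rate * seg_len / DAYS_PER_YEAR
    cum = np.cumsum(dh, axis=1)
    e = rng.exponential(size=n)
    died = cum[:, -1] >= e
    j = np.argmax(cum >= e[:, None], axis=1)
    prev = np.where(j > 0, np.take_along_axis(cum, np.maximum(j - 1, 0)[:, None], 1)[:, 0], 0.0)
    r = np.take_along_axis(rate, j[:, None], 1)[:, 0]
    t0 = np.take_along_axis(cand[:, :-1], j[:, None], 1)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        dday = t0 + (e - prev) / r * DAYS_PER_YEAR
    dday = np.minimum(np.floor(dday), horizon_day - 1)
    dday = np.maximum(dday, birth_day)
    out = np.full(n, np.nan)
    out[died] = dday[died]
    return out


# ---------------------------------------------------------------------------
# survey generation
# ---------------------------------------------------------------------------

def _snap_day15(days: np.ndarray) -> np.ndarray:
    """Snap day counts to the 15th of their calendar month."""
    d = pd.to_datetime(np.asarray(days, dtype="int64"), unit="D")
    snapped = pd.to_datetime({"year": d.year, "month": d.month, "day": 15})
    return snapped.values.astype("datetime64[D]").astype("int64")


def _day_ym(days: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = pd.to_datetime(np.asarray(days, dtype="int64"), unit="D")
    return d.year.values, d.month.values


def generate_survey(config: SimConfig):
    """Generate (respondents, relatives, truth) under ``config``.

    ``truth`` is a dict of DataFrames: the hazard and fertility schedules
    actually used, per-relative true status/dates, and scalar parameters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    compiled = _compile_schedule(config.hazard_schedule)
    n = config.n_respondents

    c0, c1 = date_to_day(config.collection_start), date_to_day(config.collection_end)
    completion_day = rng.integers(c0, c1 + 1, n)
    resp_age = rng.integers(18, 50, n)
    resp_birth = completion_day - np.round((resp_age + 0.5) * DAYS_PER_YEAR).astype("int64")
    generation = rng.choice([1, 2, 3, 4], n, p=_GENERATION_P)
    urban = rng.random(n) < config.urban_fraction
    residence = np.where(urban, "urban", "rural")
    assets = {
        item: (
            rng.random(n)
            < np.where(urban, config.asset_model["urban"][item], config.asset_model["rural"][item])
        ).astype(int)
        for item in ASSET_ITEMS
    }
    has_spouse = rng.random(n) < config.spouse_fraction

    resp_ids = np.array([f"R{i + 1:05d}" for i in range(n)])
    respondents = pd.DataFrame(
        {
            "respondent_id": resp_ids,
            "family_id": np.char.add(resp_ids.astype(str), "-F0"),
            "eligible_age": True,
            "diaspora_member": True,
            "duplicate_family": False,
            "consented": True,
            "completed": True,
            "generation": generation,
            "completion_date": pd.to_datetime(completion_day, unit="D"),
            "has_spouse_roster": has_spouse,
            "residence": residence,
            **assets,
        }
    )

    # --- families: one per respondent, plus one per reported spouse ---
    sp_idx = np.flatnonzero(has_spouse)
    sp_age = np.clip(resp_age[sp_idx] + np.round(rng.normal(0, 4, len(sp_idx))), 18, 60)
    sp_birth = completion_day[sp_idx] - np.round((sp_age + 0.5) * DAYS_PER_YEAR).astype("int64")

    fam_resp = np.concatenate([np.arange(n), sp_idx])  # respondent index per family
    fam_source = np.array(["respondent"] * n + ["spouse"] * len(sp_idx))
    fam_anchor = np.concatenate([resp_birth, sp_birth]).astype("int64")
    fam_tag = np.array(["-F0"] * n + ["-F1"] * len(sp_idx))
    nf = len(fam_resp)
    fam_ids = np.char.add(resp_ids[fam_resp].astype(str), fam_tag)
    fam_completion = completion_day[fam_resp]
    # The hazard schedule specifies in-region mortality. A fraction
    # `outside_tigray_prob` of deaths belongs to relatives who had left the
    # region (excluded from the primary analysis), so the total simulated
    # hazard is inflated by 1/(1-p); the in-region death process then runs
    # at exactly the scheduled rates.
    fam_mult = np.where(
        residence[fam_resp] == "rural", config.rural_hazard_multiplier, 1.0
    ) / (1.0 - min(config.outside_tigray_prob, 0.999))

    # --- parents (mother, father per family) ---
    mother_birth = fam_anchor - np.round((20.0 + rng.uniform(0, 15, nf)) * DAYS_PER_YEAR).astype("int64")
    father_birth = mother_birth - np.round(rng.uniform(0, 8, nf) * DAYS_PER_YEAR).astype("int64")
    par_birth = _snap_day15(np.concatenate([mother_birth, father_birth]))
    par_sex = np.concatenate([np.ones(nf, dtype=int), np.zeros(nf, dtype=int)])  # 1=female
    par_fam = np.tile(np.arange(nf), 2)

    # --- siblings ---
    sib_count = rng.poisson(config.sibling_mean, nf)
    sib_fam = np.repeat(np.arange(nf), sib_count)
    ns = len(sib_fam)
    sib_birth = _snap_day15(
        fam_anchor[sib_fam] + np.round(rng.normal(0, 5 * DAYS_PER_YEAR, ns)).astype("int64")
    )
    sib_sex = rng.integers(0, 2, ns)  # 0=male 1=female

    # --- simulate parent + sibling lifespans ---
    ps_birth = np.concatenate([par_birth, sib_birth])
    ps_sex = np.concatenate([par_sex, sib_sex])
    ps_fam = np.concatenate([par_fam, sib_fam])
    ps_death = simulate_lifespans(
        ps_birth, ps_sex, fam_completion[ps_fam], compiled, rng, fam_mult[ps_fam]
    )
    par_death, sib_death = ps_death[: 2 * nf], ps_death[2 * nf :]

    # --- nieces/nephews born to siblings through the fertility process ---
    sib_end = np.where(np.isnan(sib_death), fam_completion[sib_fam], sib_death)
    kid_parent = []
    kid_birth = []
    for row in config.fertility_schedule.itertuples(index=False):
        lo = sib_birth + np.round(row.age_lo_y * DAYS_PER_YEAR).astype("int64")
        hi = np.minimum(sib_end, sib_birth + np.round(row.age_hi_y * DAYS_PER_YEAR))
        span = np.clip(hi - lo, 0, None)
        k = rng.poisson(row.rate * span / DAYS_PER_YEAR)
        par = np.repeat(np.arange(ns), k)
        t = lo[par] + rng.random(len(par)) * span[par]
        kid_parent.append(par)
        kid_birth.append(np.floor(t).astype("int64"))
    kid_parent = np.concatenate(kid_parent) if kid_parent else np.empty(0, dtype=int)
    kid_birth_raw = np.concatenate(kid_birth) if kid_birth else np.empty(0, dtype="int64")
    order = np.argsort(kid_parent, kind="stable")
    kid_parent, kid_birth_raw = kid_parent[order], kid_birth_raw[order]
    nk = len(kid_parent)
    kid_birth = _snap_day15(kid_birth_raw) if nk else kid_birth_raw
    kid_fam = sib_fam[kid_parent] if nk else np.empty(0, dtype=int)
    kid_sex = rng.integers(0, 2, nk)
    kid_death = simulate_lifespans(
        kid_birth, kid_sex, fam_completion[kid_fam], compiled, rng, fam_mult[kid_fam]
    )

    # --- assemble the roster ---
    relation = np.concatenate(
        [
            np.repeat("parent", 2 * nf),
            np.repeat("sibling", ns),
            np.repeat("niece_nephew", nk),
        ]
    )
    birth = np.concatenate([par_birth, sib_birth, kid_birth]).astype("int64")
    true_sex = np.concatenate([par_sex, sib_sex, kid_sex])
    fam = np.concatenate([par_fam, sib_fam, kid_fam]).astype(int)
    death = np.concatenate([par_death, sib_death, kid_death])
    m = len(relation)
    rel_ids = np.array([f"L{i + 1:06d}" for i in range(m)])
    sib_rel_ids = rel_ids[2 * nf : 2 * nf + ns]
    linked = np.full(m, "", dtype=object)
    if nk:
        linked[2 * nf + ns :] = sib_rel_ids[kid_parent]

    died = ~np.isnan(death)
    comp = fam_completion[fam]

    # reporting noise
    unknown = rng.random(m) < config.unknown_status_prob
    sex_unk = (rng.random(m) < config.sex_unknown_prob) & (relation != "parent")
    age_only = rng.random(m) < config.age_only_prob
    month_missing = rng.random(m) < config.month_missing_prob

    status = np.where(unknown, "unknown", np.where(died, "deceased", "alive"))
    rep_died = died & ~unknown

    by, bm = _day_ym(birth)
    dday = np.where(died, death, 0).astype("int64")
    dy, dm = _day_ym(dday)
    age_surv = np.floor((comp - birth) / DAYS_PER_YEAR).astype(int)
    age_death = np.floor((dday - birth) / DAYS_PER_YEAR).astype(int)

    # location and cause (reported deaths only)
    outside = rng.random(m) < config.outside_tigray_prob
    zones = list(config.zone_distribution)
    zp = np.array([config.zone_distribution[z] for z in zones])
    zone_draw = rng.choice(zones, m, p=zp / zp.sum())
    location = np.where(outside, "outside_tigray", zone_draw)
    war_day = date_to_day(config.war_start)
    in_war = died & (dday >= war_day) & ~outside
    u = rng.random(m)
    inj = config.war_injury_fraction
    war_cut = np.cumsum([inj] + [_WAR_CAUSE_P[c] * (1 - inj) / sum(_WAR_CAUSE_P.values()) for c in _WAR_CAUSE_P])
    pre_names = list(_PREWAR_CAUSE_P)
    pre_cut = np.cumsum([_PREWAR_CAUSE_P[c] for c in pre_names])
    war_names = ["intentional_injury"] + list(_WAR_CAUSE_P)
    cause_war = np.array(war_names, dtype=object)[np.searchsorted(war_cut, u, side="right").clip(0, 3)]
    cause_pre = np.array(pre_names, dtype=object)[np.searchsorted(pre_cut, u, side="right").clip(0, 3)]
    cause = np.where(in_war, cause_war, cause_pre)

    sex = np.where(sex_unk, "unknown", np.where(true_sex == 1, "female", "male"))
    alive_like = ~rep_died

    relatives = pd.DataFrame(
        {
            "relative_id": rel_ids,
            "respondent_id": resp_ids[fam_resp[fam]],
            "family_id": fam_ids[fam],
            "roster_source": fam_source[fam],
            "relation": relation,
            "linked_sibling_id": linked,
            "sex": sex,
            "birth_year": np.where(age_only, np.nan, by),
            "birth_month": np.where(age_only, np.nan, bm),
            "age_at_survey": np.where(alive_like & age_only, age_surv, np.nan),
            "status": status,
            "death_year": np.where(rep_died, dy, np.nan),
            "death_month": np.where(rep_died & ~month_missing, dm, np.nan),
            "age_at_death": np.where(rep_died, age_death, np.nan),
            "cause": np.where(rep_died, cause, ""),
            "location_of_death": np.where(rep_died, location, ""),
        }
    )

    true_death = pd.Series(pd.NaT, index=np.arange(m), dtype="datetime64[ns]")
    true_death[died] = pd.to_datetime(death[died].astype("int64"), unit="D")
    truth = {
        "hazards": config.hazard_schedule.copy(),
        "fertility": config.fertility_schedule.copy(),
        "relatives": pd.DataFrame(
            {
                "relative_id": rel_ids,
                "true_status": np.where(died, "deceased", "alive"),
                "true_birth": pd.to_datetime(birth, unit="D"),
                "true_death": true_death,
                "masked_unknown": unknown,
            }
        ),
        "params": config.scalar_params(),
    }
    return respondents, relatives, truth


def generate_reference(config: SimConfig, n: int) -> pd.DataFrame:
    """Reference-population sample (residence + asset items), emulating a
    regional household-survey subsample; reproducible under config.seed."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    config.validate()
    rng = np.random.default_rng([config.seed, 1009])
    urban = rng.random(n) < config.reference_urban_fraction
    out = {"residence": np.where(urban, "urban", "rural")}
    for item in ASSET_ITEMS:
        p = np.where(urban, config.asset_model["urban"][item], config.asset_model["rural"][item])
        out[item] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# packaged tabulation fixture
# ---------------------------------------------------------------------------

# Relation x roster-source x status counts of the published roster.
_T2 = {
    ("respondent", "sibling"): (2780, 266, 343),
    ("respondent", "niece_nephew"): (3630, 96, 396),
    ("respondent", "parent"): (1048, 461, 73),
    ("spouse", "sibling"): (531, 57, 69),
    ("spouse", "niece_nephew"): (572, 17, 62),
    ("spouse", "parent"): (189, 114, 21),
}

_WAR_ZONE_COUNTS = [
    ("central", 134),
    ("eastern", 61),
    ("southern_southeastern", 32),
    ("north_western", 26),
    ("mekelle", 26),
    ("western", 25),
    ("unknown_zone", 6),
]

# War-period in-Tigray deaths: (age_group, sex, cause, count). Printed
# marginals are exact (310 total; 224 injuries of which 149 male; adults
# 15-49: 165 deaths, 105 male with 97 injuries, 60 female with 48); the
# remaining joint cells are a synthetic completion.
_WAR_CELLS = [
    ("adult", "male", "intentional_injury", 97),
    ("adult", "male", "starvation_disease", 6),
    ("adult", "male", "other", 1),
    ("adult", "male", "unknown", 1),
    ("adult", "female", "intentional_injury", 48),
    ("adult", "female", "starvation_disease", 9),
    ("adult", "female", "other", 2),
    ("adult", "female", "unknown", 1),
    ("older", "male", "intentional_injury", 52),
    ("older", "female", "intentional_injury", 27),
    ("older", "male", "starvation_disease", 25),
    ("older", "female", "starvation_disease", 24),
    ("older", "male", "other", 6),
    ("older", "female", "other", 5),
    ("older", "male", "unknown", 3),
    ("older", "female", "unknown", 3),
]


def _fixture_death_lists():
    """Per-relation death record lists honouring every printed aggregate."""
    zone_seq = [z for z, c in _WAR_ZONE_COUNTS for _ in range(c)]
    war = []
    for age_group, sex, cause, count in _WAR_CELLS:
        for _ in range(count):
            war.append(
                {
                    "sex": sex,
                    "cause": cause,
                    "death_year": 2021,
                    "death_month": 6,
                    "age_at_death": 30 if age_group == "adult" else 70,
                    "location_of_death": zone_seq[len(war)],
                }
            )
    assert len(war) == 310

    def prewar(n, age, sexes=("male", "female")):
        return [
            {
                "sex": sexes[i % 2],
                "cause": "starvation_disease",
                "death_year": 2012,
                "death_month": 5,
                "age_at_death": age,
                "location_of_death": "central",
            }
            for i in range(n)
        ]

    outside = [
        {
            "sex": ("male", "female")[i % 2],
            "cause": "other",
            "death_year": 2021,
            "death_month": 1,
            "age_at_death": 75,
            "location_of_death": "outside_tigray",
        }
        for i in range(201)
    ]
    deaths = {
        "sibling": [w for w in war if w["age_at_death"] == 30] + prewar(158, 30),
        "niece_nephew": prewar(113, 6),
        "parent": [w for w in war if w["age_at_death"] == 70] + prewar(229, 70) + outside,
    }
    assert len(deaths["sibling"]) == 323
    assert len(deaths["parent"]) == 575
    return deaths


def build_paper_fixture() -> dict[str, pd.DataFrame]:
    """Record-level fixture transcribing the survey's printed aggregates.

    Returns ``{"accesses", "respondents", "relatives"}``. Every printed
    marginal (eligibility/attrition partition, relation x source x status
    counts, death location/period/cause/sex/zone tabulations) is reproduced
    exactly; joint cells the publication does not pin down are a synthetic,
    deterministic completion.
    """
    # --- survey access log (eligibility, attrition, propagation) ---
    rows = []
    aid = 0

    def access(n, **kw):
        nonlocal aid
        base = {
            "eligible_age": True,
            "diaspora_member": True,
            "duplicate_family": False,
            "consented": False,
            "completed": False,
            "generation": 1,
        }
        base.update(kw)
        for _ in range(n):
            aid += 1
            rows.append({"access_id": f"A{aid:04d}", **base})

    access(114, eligible_age=False)
    access(18, diaspora_member=False)
    access(79, duplicate_family=True)
    access(31)  # eligible, did not consent
    access(18, consented=True)  # consented, did not complete
    for gen, cnt in [(1, 699), (2, 74), (3, 14), (4, 4)]:
        access(cnt, consented=True, completed=True, generation=gen)
    accesses = pd.DataFrame(rows)
    assert len(accesses) == 1051

    # --- respondents ---
    resp_ids = [f"R{i + 1:04d}" for i in range(791)]
    respondents = pd.DataFrame(
        {
            "respondent_id": resp_ids,
            "family_id": [r + "-F0" for r in resp_ids],
            "eligible_age": True,
            "diaspora_member": True,
            "duplicate_family": False,
            "consented": True,
            "completed": True,
            "generation": 1,
            "completion_date": pd.Timestamp("2023-01-15"),
            "has_spouse_roster": [i < 162 for i in range(791)],
            "residence": ["urban" if i % 4 else "rural" for i in range(791)],
        }
    )

    # --- relatives ---
    deaths = _fixture_death_lists()
    used = {k: 0 for k in deaths}
    alive_age = {"sibling": 32, "niece_nephew": 12, "parent": 68}
    recs = []
    rid = 0
    for (source, relation), (n_alive, n_dec, n_unk) in _T2.items():
        pool = 162 if source == "spouse" else 791
        for kind, count in (("alive", n_alive), ("deceased", n_dec), ("unknown", n_unk)):
            for i in range(count):
                rid += 1
                rec = {
                    "relative_id": f"L{rid:05d}",
                    "respondent_id": resp_ids[(rid - 1) % pool],
                    "roster_source": source,
                    "relation": relation,
                    "linked_sibling_id": "",
                    "sex": ("male", "female")[i % 2],
                    "birth_year": np.nan,
                    "birth_month": np.nan,
                    "age_at_survey": np.nan,
                    "status": kind,
                    "death_year": np.nan,
                    "death_month": np.nan,
                    "age_at_death": np.nan,
                    "cause": "",
                    "location_of_death": "",
                }
                if kind == "deceased":
                    d = deaths[relation][used[relation]]
                    used[relation] += 1
                    rec.update(d)
                else:
                    rec["age_at_survey"] = alive_age[relation]
                rec["family_id"] = rec["respondent_id"] + ("-F1" if source == "spouse" else "-F0")
                recs.append(rec)
    relatives = pd.DataFrame(recs)
    assert len(relatives) == 10725
    assert (relatives["status"] == "deceased").sum() == 1011
    return {"accesses": accesses, "respondents": respondents, "relatives": relatives}
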