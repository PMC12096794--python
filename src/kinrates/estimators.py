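"""Mortality estimators.

Child and young-cohort mortality uses the synthetic-cohort construction:
the probability of dying over an age span within a calendar period is one
minus the product of stratum-specific survival probabilities, where each
stratum's risk set counts person-entries fractionally (stratum person-time
divided by stratum width). Adult and older-adult mortality is the ratio of
deaths to person-time. Confidence intervals are percentile intervals over
respondent-level (cluster) bootstrap resamples: a resample draws respondent
ids with replacement, and all of a respondent's relatives — spouse roster
included — travel with them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kinrates.exposure import (
    CHILD_5_14_STRATA,
    U5_STRATA,
    YOUTH_15_24_STRATA,
    AgeStratum,
    Period,
    cell_exposure,
)

SPAN_STRATA = {"U5": U5_STRATA, "5-14": CHILD_5_14_STRATA, "15-24": YOUTH_15_24_STRATA}


@dataclass
class ProbabilityEstimate:
    span: str
    period: str
    q_per_1000: float
    ci_lo: float = np.nan
    ci_hi: float = np.nan
    strata: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_denominator: float = 0.0
    undefined: bool = False
    standardised: bool = False


@dataclass
class RateEstimate:
    period: str
    age_lo_y: int
    age_hi_y: int
    sex: str
    rate_per_1000py: float
    ci_lo: float = np.nan
    ci_hi: float = np.nan
    deaths: float = 0.0
    person_years: float = 0.0
    undefined: bool = False
    standardised: bool = False


@dataclass
class BootstrapCI:
    lo: float
    hi: float
    replicates: np.ndarray
    n_dropped: int


# ---------------------------------------------------------------------------
# point estimators
# ---------------------------------------------------------------------------

def _weights(resolved: pd.DataFrame) -> np.ndarray:
    if "weight" in resolved.columns:
        return resolved["weight"].to_numpy(dtype=float)
    return np.ones(len(resolved))


def stratum_stats(
    resolved: pd.DataFrame, period: Period, strata: list[AgeStratum]
) -> pd.DataFrame:
    """Deaths and fractional risk-set size per age stratum within a period."""
    w = _weights(resolved)
    rows = []
    for s in strata:
        py, dth = cell_exposure(resolved, period, s)
        rows.append(
            {
                "age_lo_m": s.lo,
                "age_hi_m": s.hi,
                "deaths": float((w * dth).sum()),
                "person_years": float((w * py).sum()),
                "n_risk": float((w * py).sum() / s.width_years),
            }
        )
    return pd.DataFrame(rows)


def q_from_strata(strata: pd.DataFrame) -> float:
    """Synthetic-cohort probability: 1 - prod(1 - d_a / n_a), NaN if every
    stratum risk set is empty."""
    d = strata["deaths"].to_numpy(dtype=float)
    n = strata["n_risk"].to_numpy(dtype=float)
    if np.all(n <= 0):
        return np.nan
    qa = np.divide(d, n, out=np.zeros_like(d), where=n > 0)
    qa = np.clip(qa, 0.0, 1.0)
    return float(1.0 - np.prod(1.0 - qa))


def child_mortality(
    resolved: pd.DataFrame, period: Period, span: str = "U5"
) -> ProbabilityEstimate:
    """Period mortality probability over an age span, per 1000.

    ``resolved`` should contain the child cohort records (nieces/nephews).
    Conditional spans (5-14, 15-24) are automatic: children dying before the
    span's lower bound contribute neither deaths nor risk time to it.
    """
    if span not in SPAN_STRATA:
        raise ValueError(f"unknown span {span!r}; expected one of {sorted(SPAN_STRATA)}")
    st = stratum_stats(resolved, period, SPAN_STRATA[span])
    q = q_from_strata(st)
    return ProbabilityEstimate(
        span=span,
        period=period.label,
        q_per_1000=q * 1000.0 if np.isfinite(q) else np.nan,
        strata=st,
        n_denominator=float(st["n_risk"].sum()),
        undefined=not np.isfinite(q),
    )


def period_rate(
    ledger: pd.DataFrame,
    period: str,
    age_range_years: tuple[int, int] = (15, 50),
    sex: str | None = None,
) -> RateEstimate:
    """Deaths per 1000 person-years from a person-time ledger.

    Sums every ledger cell of the named period whose age band lies inside
    ``age_range_years``. ``sex=None`` aggregates all sexes (unknown
    included); otherwise only the named level is used.
    """
    lo, hi = age_range_years
    sub = ledger[
        (ledger["period"] == period)
        & (ledger["age_lo_m"] >= lo * 12)
        & (ledger["age_hi_m"] <= hi * 12)
    ]
    if sub.empty:
        raise ValueError(f"ledger has no cells for period {period!r} in ages [{lo}, {hi})")
    if sex is not None:
        sub = sub[sub["sex"] == sex]
    d, py = float(sub["deaths"].sum()), float(sub["person_years"].sum())
    return RateEstimate(
        period=period,
        age_lo_y=lo,
        age_hi_y=hi,
        sex=sex or "all",
        rate_per_1000py=1000.0 * d / py if py > 0 else np.nan,
        deaths=d,
        person_years=py,
        undefined=py <= 0,
    )


def rate_from_resolved(
    resolved: pd.DataFrame,
    period: Period,
    age_range_years: tuple[int, int] = (15, 50),
    sex: str | None = None,
) -> RateEstimate:
    """Deaths per 1000 person-years computed directly from resolved records
    (honours a ``weight`` column; used by the standardised pipeline)."""
    lo, hi = age_range_years
    sub = resolved if sex is None else resolved[resolved["sex"] == sex]
    py, dth = cell_exposure(sub, period, AgeStratum(lo * 12, hi * 12))
    w = _weights(sub)
    d, p = float((w * dth).sum()), float((w * py).sum())
    return RateEstimate(
        period=period.label,
        age_lo_y=lo,
        age_hi_y=hi,
        sex=sex or "all",
        rate_per_1000py=1000.0 * d / p if p > 0 else np.nan,
        deaths=d,
        person_years=p,
        undefined=p <= 0,
    )


# ---------------------------------------------------------------------------
# respondent-level bootstrap
# ---------------------------------------------------------------------------

def _percentile_interval(reps: np.ndarray, level: float) -> tuple[float, float]:
    """Percentile interval with the conventional (B+1) order-statistic
    endpoints: [r(floor((B+1)a/2)), r(ceil((B+1)(1-a/2)))], a = 1-level.
    Both endpoints are order statistics of the replicate distribution."""
    a = (1.0 - level) / 2.0
    b = len(reps)
    srt = np.sort(reps)
    k_lo = max(int(np.floor((b + 1) * a)), 1)
    k_hi = min(int(np.ceil((b + 1) * (1.0 - a))), b)
    return float(srt[k_lo - 1]), float(srt[k_hi - 1])


def bootstrap_ci(
    estimator,
    respondents: pd.DataFrame,
    relatives: pd.DataFrame,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Respondent-cluster percentile bootstrap of an arbitrary estimator.

    ``estimator(respondents, relatives) -> float`` must be a pure function
    of the pair. Each replicate draws respondent ids with replacement
    (sized as the original respondent count) and carries every relative of
    each drawn respondent. Replicates evaluating to NaN (e.g. empty
    denominators) are dropped; their count is reported.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    ids = respondents["respondent_id"].to_numpy()
    n = len(ids)
    codes = pd.Categorical(relatives["respondent_id"], categories=ids).codes
    if (codes < 0).any():
        raise ValueError("relatives reference respondents missing from the respondent frame")
    order = np.argsort(codes, kind="stable")
    sorted_rel = relatives.iloc[order].reset_index(drop=True)
    counts = np.bincount(codes, minlength=n)
    indptr = np.concatenate([[0], np.cumsum(counts)])

    reps = np.empty(B)
    for b in range(B):
        draw = rng.integers(0, n, n)
        take = np.concatenate([np.arange(indptr[i], indptr[i + 1]) for i in draw])
        rel_b = sorted_rel.iloc[take]
        resp_b = respondents.iloc[draw]
        reps[b] = estimator(resp_b, rel_b)
    good = reps[np.isfinite(reps)]
    if len(good) == 0:
        return BootstrapCI(np.nan, np.nan, reps, B)
    lo, hi = _percentile_interval(good, level)
    return BootstrapCI(lo, hi, reps, int(B - len(good)))


def cluster_bootstrap(
    stats: np.ndarray,
    reduce,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Vectorised cluster bootstrap over per-respondent sufficient statistics.

    ``stats`` has one row per respondent; a replicate sums resampled rows
    and applies ``reduce(sums) -> estimate`` (vectorised over a (B, k)
    array). For estimators that are functions of cluster-wise sums — every
    rate and synthetic-cohort probability here — this is exactly equivalent
    to :func:`bootstrap_ci`, replicate for replicate under the same seed.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    n = stats.shape[0]
    draws = rng.integers(0, n, (B, n))
    sums = stats[draws].sum(axis=1)
    reps = np.asarray(reduce(sums), dtype=float)
    good = reps[np.isfinite(reps)]
    if len(good) == 0:
        return BootstrapCI(np.nan, np.nan, reps, B)
    lo, hi = _percentile_interval(good, level)
    return BootstrapCI(lo, hi, reps, int(B - len(good)))


def respondent_sums(resolved: pd.DataFrame, respondents: pd.DataFrame, cols: np.ndarray) -> np.ndarray:
    """Sum per-relative statistics (rows of ``cols``) within respondents."""
    ids = respondents["respondent_id"].to_numpy()
    codes = pd.Categorical(resolved["respondent_id"], categories=ids).codes
    out = np.zeros((len(ids), cols.shape[1]))
    np.add.at(out, codes, cols)
    return out


def rate_with_ci(
    respondents: pd.DataFrame,
    resolved: pd.DataFrame,
    period: Period,
    age_range_years: tuple[int, int] = (15, 50),
    sex: str | None = None,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> RateEstimate:
    """Period rate with a respondent-cluster percentile bootstrap CI."""
    lo_y, hi_y = age_range_years
    sub = resolved if sex is None else resolved[resolved["sex"] == sex]
    py, dth = cell_exposure(sub, period, AgeStratum(lo_y * 12, hi_y * 12))
    w = _weights(sub)
    stats = respondent_sums(sub, respondents, np.column_stack([w * py, w * dth]))
    est = period_rate_reduce(stats.sum(axis=0)[None, :])[0]
    ci = cluster_bootstrap(stats, period_rate_reduce, B=B, level=level, seed=seed)
    return RateEstimate(
        period=period.label,
        age_lo_y=lo_y,
        age_hi_y=hi_y,
        sex=sex or "all",
        rate_per_1000py=float(est),
        ci_lo=ci.lo,
        ci_hi=ci.hi,
        deaths=float((w * dth).sum()),
        person_years=float((w * py).sum()),
        undefined=not np.isfinite(est),
    )


def period_rate_reduce(sums: np.ndarray) -> np.ndarray:
    """(B, 2) array of [person_years, deaths] sums -> rates per 1000 py."""
    py, d = sums[:, 0], sums[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(py > 0, 1000.0 * d / py, np.nan)


def child_mortality_with_ci(
    respondents: pd.DataFrame,
    resolved: pd.DataFrame,
    period: Period,
    span: str = "U5",
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> ProbabilityEstimate:
    """Synthetic-cohort probability with a respondent-cluster bootstrap CI."""
    est = child_mortality(resolved, period, span)
    strata = SPAN_STRATA[span]
    w = _weights(resolved)
    cols = []
    for s in strata:
        py, dth = cell_exposure(resolved, period, s)
        cols += [w * py / s.width_years, w * dth]
    stats = respondent_sums(resolved, respondents, np.column_stack(cols))

    def reduce(sums: np.ndarray) -> np.ndarray:
        n_a = sums[:, 0::2]
        d_a = sums[:, 1::2]
        with np.errstate(divide="ignore", invalid="ignore"):
            qa = np.where(n_a > 0, d_a / n_a, 0.0)
        qa = np.clip(qa, 0.0, 1.0)
        q = 1.0 - np.prod(1.0 - qa, axis=1)
        return np.where((n_a > 0).any(axis=1), 1000.0 * q, np.nan)

    ci = cluster_bootstrap(stats, reduce, B=B, level=level, seed=seed)
    est.ci_lo, est.ci_hi = ci.lo, ci.hi
    return est
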