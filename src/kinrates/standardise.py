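"""Post-stratification by urban/rural residence and asset-based wealth index.

The diaspora sample over-represents urban, wealthier families. To reduce
this selection bias, asset items are completed by chained-equations
imputation with random-forest conditional models, a wealth index is built
per residence stratum by principal components on the pooled survey +
reference covariance matrix (varimax-rotated, up to three components, the
first rotated component as the index), quintiles are cut on the pooled
score distribution, and each (residence x quintile) stratum receives a
weight equal to its share of the reference sample. Estimates are
standardised by weighting deaths and person-time jointly at family level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from statsmodels.multivariate.factor_rotation import rotate_factors


# ---------------------------------------------------------------------------
# chained-equations imputation
# ---------------------------------------------------------------------------

def impute_assets(
    assets: pd.DataFrame,
    n_chains: int = 5,
    n_iter: int = 20,
    seed: int | None = None,
    n_estimators: int = 30,
) -> pd.DataFrame:
    """Complete a categorical asset matrix by chained equations.

    Each chain initialises missing cells by sampling observed values, then
    cycles ``n_iter`` times over items with missingness, refitting a
    random-forest classifier of each item on all others and overwriting the
    missing cells with its predictions. Chains are combined cell-wise by
    mode (the downstream use is quintile classification, not variance
    estimation). An item with no observed values is rejected by name.
    """
    if assets.isna().all().any():
        item = assets.columns[assets.isna().all()][0]
        raise ValueError(f"asset item {item!r} is entirely missing; cannot impute")
    miss = assets.isna()
    if not miss.any().any():
        return assets.copy()
    rng = np.random.default_rng(seed)
    cols = list(assets.columns)
    completions = []
    for _ in range(n_chains):
        df = assets.copy()
        for c in cols:
            m = miss[c]
            if m.any():
                obs = df.loc[~m, c].to_numpy()
                df.loc[m, c] = rng.choice(obs, int(m.sum()))
        for _ in range(n_iter):
            for c in cols:
                m = miss[c]
                if not m.any():
                    continue
                X = df.drop(columns=[c]).to_numpy(dtype=float)
                y = df[c].to_numpy()
                clf = RandomForestClassifier(
                    n_estimators=n_estimators,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                    n_jobs=1,
                )
                clf.fit(X[~m.to_numpy()], y[~m.to_numpy()])
                df.loc[m, c] = clf.predict(X[m.to_numpy()])
        completions.append(df)
    out = assets.copy()
    for c in cols:
        m = miss[c]
        if m.any():
            stacked = np.column_stack([comp.loc[m, c].to_numpy() for comp in completions])
            mode = pd.DataFrame(stacked).mode(axis=1)[0].to_numpy()
            out.loc[m, c] = mode
    return out


# ---------------------------------------------------------------------------
# wealth index
# ---------------------------------------------------------------------------

@dataclass
class WealthModel:
    """Per-residence-stratum wealth index: rotated PCA loadings, a sign
    orientation, and quintile cut-points from the pooled score distribution."""

    residence: str
    items: list[str]
    mean: np.ndarray
    loadings: np.ndarray  # (n_items, n_components), varimax-rotated
    index_component: int
    sign: float
    quintile_cuts: np.ndarray  # 4 interior cut-points

    def score(self, X: pd.DataFrame) -> np.ndarray:
        Z = X[self.items].to_numpy(dtype=float) - self.mean
        return self.sign * (Z @ self.loadings[:, self.index_component])

    def quintile(self, X: pd.DataFrame) -> np.ndarray:
        return np.searchsorted(self.quintile_cuts, self.score(X), side="right") + 1


@dataclass
class WealthIndex:
    models: dict = field(default_factory=dict)  # residence -> WealthModel

    def assign_strata(self, df: pd.DataFrame) -> pd.Series:
        """Map rows (residence + items) to 'urban_q3'-style stratum labels."""
        out = pd.Series(index=df.index, dtype=object)
        for res, model in self.models.items():
            m = df["residence"] == res
            if m.any():
                out[m] = [f"{res}_q{q}" for q in model.quintile(df[m])]
        if out.isna().any():
            bad = df.loc[out.isna(), "residence"].unique()
            raise ValueError(f"rows with unmodelled residence stratum: {list(bad)}")
        return out


def _fit_stratum(pooled: pd.DataFrame, items: list[str], residence: str, n_components: int = 3) -> WealthModel:
    X = pooled[items].to_numpy(dtype=float)
    keep = [i for i, c in enumerate(items) if np.std(X[:, i]) > 0]
    dropped = [c for i, c in enumerate(items) if i not in keep]
    if dropped:
        warnings.warn(f"{residence}: dropping constant asset items {dropped}")
    if not keep:
        raise ValueError(f"{residence}: all asset items constant; wealth index undefined")
    use = [items[i] for i in keep]
    X = X[:, keep]
    mean = X.mean(axis=0)
    Z = X - mean
    cov = np.cov(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(vals)[::-1]
    k = min(n_components, len(use))
    L = vecs[:, order[:k]] * np.sqrt(np.maximum(vals[order[:k]], 0.0))
    if k > 1:
        L, _ = rotate_factors(L, "varimax")
    ss = (L**2).sum(axis=0)
    comp = int(np.argmax(ss))
    raw = Z @ L[:, comp]
    count = X.sum(axis=1)
    corr = np.corrcoef(raw, count)[0, 1] if np.std(raw) > 0 and np.std(count) > 0 else 1.0
    sign = -1.0 if corr < 0 else 1.0
    scores = sign * raw
    cuts = np.quantile(scores, [0.2, 0.4, 0.6, 0.8])
    return WealthModel(
        residence=residence,
        items=use,
        mean=mean,
        loadings=L,
        index_component=comp,
        sign=sign,
        quintile_cuts=cuts,
    )


def fit_wealth(
    survey_assets: pd.DataFrame,
    reference_assets: pd.DataFrame,
    items: list[str],
    n_components: int = 3,
) -> WealthIndex:
    """Fit one wealth model per residence stratum on the pooled data.

    Both frames need a ``residence`` column plus identical ``items``. The
    index is the score on the first varimax-rotated principal component
    (largest squared loadings after rotation), oriented so that a higher
    index means more assets owned.
    """
    missing = [c for c in items if c not in survey_assets.columns or c not in reference_assets.columns]
    if missing:
        raise ValueError(f"item sets differ between survey and reference: {missing}")
    pooled = pd.concat(
        [survey_assets[["residence"] + items], reference_assets[["residence"] + items]],
        ignore_index=True,
    )
    models = {}
    for res in sorted(pooled["residence"].unique()):
        models[res] = _fit_stratum(pooled[pooled["residence"] == res], items, res, n_components)
    return WealthIndex(models)


# ---------------------------------------------------------------------------
# post-stratification weights
# ---------------------------------------------------------------------------

@dataclass
class WeightTable:
    """Stratum -> weight (reference proportions; non-negative, sum 1)."""

    table: pd.DataFrame  # stratum, weight

    def as_series(self) -> pd.Series:
        return self.table.set_index("stratum")["weight"]


def make_weights(reference_strata: pd.Series) -> WeightTable:
    """Weights equal to the proportion of reference observations per stratum."""
    w = reference_strata.value_counts(normalize=True).sort_index()
    return WeightTable(pd.DataFrame({"stratum": w.index, "weight": w.values}))


def survey_weight_factors(
    survey_strata: pd.Series, weights: WeightTable
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-record factors w(stratum)/p_survey(stratum).

    Reference weight attached to a stratum absent from the survey is
    redistributed proportionally across occupied strata; the log of
    redistributed strata is returned alongside.
    """
    w = weights.as_series()
    p = survey_strata.value_counts(normalize=True)
    occupied = w.index.intersection(p.index)
    lost = w.index.difference(p.index)
    log = pd.DataFrame({"stratum": lost, "weight_redistributed": w[lost].values})
    w_occ = w[occupied]
    w_occ = w_occ / w_occ.sum()
    factors = survey_strata.map(w_occ / p[occupied])
    if factors.isna().any():
        # survey strata with no reference mass get zero weight
        factors = factors.fillna(0.0)
    return factors, log


def attach_weights(
    respondents: pd.DataFrame,
    relatives: pd.DataFrame,
    reference: pd.DataFrame,
    items: list[str],
    impute: bool = False,
    seed: int | None = None,
    **impute_kw,
) -> tuple[pd.DataFrame, WealthIndex, WeightTable]:
    """Full standardisation plumbing: (impute ->) fit index -> weights.

    The wealth stratum is attached at family level: one respondent's
    closest-family asset report covers all relatives of that respondent
    (spouse roster included). Returns relatives with a ``weight`` column.
    """
    surv = respondents[["residence"] + items].copy()
    if impute:
        surv[items] = impute_assets(surv[items], seed=seed, **impute_kw)
    index = fit_wealth(surv, reference, items)
    surv_strata = index.assign_strata(surv)
    ref_strata = index.assign_strata(reference)
    weights = make_weights(ref_strata)
    factors, _ = survey_weight_factors(surv_strata, weights)
    per_resp = pd.Series(factors.values, index=respondents["respondent_id"].values)
    out = relatives.copy()
    out["weight"] = out["respondent_id"].map(per_resp).fillna(0.0)
    return out, index, weights
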