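"""End-to-end orchestration: config-driven runs, manifests, table export.

A run executes ingest -> exposure -> estimation (-> standardisation ->
sensitivity) from a single config mapping, writes tidy delimited tables
under an output directory, and records a manifest (config snapshot, seeds,
input digests, package version, timestamp). Given the same config and
seeds the output tables are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

import kinrates
from kinrates.config import ASSET_ITEMS, SimConfig
from kinrates.estimators import child_mortality_with_ci, rate_with_ci
from kinrates.exposure import (
    OLDER_ADULT_STRATUM,
    Period,
    accumulate,
    five_year_strata,
    older_adult_periods,
    resolve_dates,
    standard_periods,
)
from kinrates.fertility import asfr, birth_intervals
from kinrates.ingest import apply_eligibility, assemble_rosters, filter_death_location_scope, tabulate_deaths
from kinrates.sensitivity import MigrationScenario, migration_sensitivity, summarise_migration
from kinrates.standardise import attach_weights
from kinrates.synthetic import generate_reference, generate_survey

log = logging.getLogger("kinrates")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, schema_note: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# kinrates v{kinrates.__version__} :: {schema_note}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a kinrates delimited table (skips the schema header comment)."""
    return pd.read_csv(path, comment="#")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the configured analysis; returns {stage: outputs} summary.

    Config keys: ``seed``; either ``simulate`` (SimConfig field overrides)
    or ``inputs`` (paths to respondents/relatives/reference tables);
    ``bootstrap`` (replicates, default 200); ``standardise`` (bool);
    ``migration`` ({proportion, simulations}). A stage failure raises with
    the stage named; tables written before the failure are retained.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config.get("out_dir", "kinrates_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    B = int(config.get("bootstrap", 200))
    manifest: dict = {
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "version": kinrates.__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {},
    }
    summary: dict = {}
    stage = "setup"
    try:
        stage = "inputs"
        if "inputs" in config:
            paths = {k: Path(v) for k, v in config["inputs"].items()}
            for k, p in paths.items():
                if not p.exists():
                    raise FileNotFoundError(f"missing input file {k!r}: {p}")
                manifest["inputs"][k] = _digest(p)
            respondents = read_table(paths["respondents"])
            relatives = read_table(paths["relatives"])
            reference = read_table(paths["reference"]) if "reference" in paths else None
        else:
            sim_kw = dict(config.get("simulate", {}))
            sim_cfg = SimConfig(**sim_kw, seed=seed)
            respondents, relatives, truth = generate_survey(sim_cfg)
            reference = generate_reference(sim_cfg, int(config.get("n_reference", 2000)))
            _write(respondents, out / "respondents.csv", "one row per analysable respondent")
            _write(relatives, out / "relatives.csv", "one row per reported relative")
            _write(reference, out / "reference.csv", "reference sample: residence + assets")
            for name, df in truth.items():
                _write(df, out / f"truth_{name}.csv", "simulation ground truth (not a survey export)")

        stage = "ingest"
        roster = assemble_rosters(respondents, relatives)
        _write(roster.table, out / "roster_counts.csv", "relation x source x status counts")
        if "accesses" in config.get("inputs", {}):
            rep = apply_eligibility(read_table(Path(config["inputs"]["accesses"])))
            _write(rep.table, out / "attrition.csv", "eligibility and attrition partition")
        completion = pd.Series(
            pd.to_datetime(respondents["completion_date"]).values,
            index=respondents["respondent_id"].values,
        )
        resolved = resolve_dates(relatives, completion)
        resolved = filter_death_location_scope(resolved, config.get("scope", "in_tigray"))
        war = standard_periods()[-1]
        tab = tabulate_deaths(resolved, period=war, scope="all")
        _write(tab.by_cause.reset_index(names="cause"), out / "war_deaths_by_cause.csv", "war-period deaths")
        summary["ingest"] = {"relatives": roster.total, "war_deaths": tab.total}

        stage = "exposure"
        ledger = accumulate(resolved[resolved["relation"] == "sibling"], standard_periods(), five_year_strata())
        _write(ledger, out / "ledger_adults.csv", "person-years and deaths per cell")

        stage = "estimates"
        kids = resolved[resolved["relation"] == "niece_nephew"]
        sibs = resolved[resolved["relation"] == "sibling"]
        parents = resolved[resolved["relation"] == "parent"]
        rows = []
        for period in standard_periods():
            for span in ("U5", "5-14", "15-24"):
                e = child_mortality_with_ci(respondents, kids, period, span, B=B, seed=seed)
                rows.append(dataclasses.asdict(e) | {"group": "children"})
            for sex in (None, "male", "female"):
                r = rate_with_ci(respondents, sibs, period, (15, 50), sex, B=B, seed=seed)
                rows.append(dataclasses.asdict(r) | {"group": "adults"})
        for period in older_adult_periods():
            r = rate_with_ci(
                respondents, parents, period,
                (OLDER_ADULT_STRATUM.lo // 12, OLDER_ADULT_STRATUM.hi // 12),
                None, B=B, seed=seed,
            )
            rows.append(dataclasses.asdict(r) | {"group": "older_adults"})
        est = pd.DataFrame(rows).drop(columns=["strata"], errors="ignore")
        _write(est, out / "estimates.csv", "mortality estimates with bootstrap CIs")
        summary["estimates"] = est

        stage = "fertility"
        frows = []
        for period in standard_periods():
            for rsex in ("female", "male"):
                f = asfr(resolved, period, rsex)
                t = f.table.assign(period=period.label, reporter_sex=rsex)
                frows.append(t)
        fert = pd.concat(frows, ignore_index=True)
        _write(fert, out / "fertility.csv", "age-specific fertility rates")
        bi = birth_intervals(resolved, standard_periods())
        if len(bi.by_period):
            _write(bi.by_period, out / "birth_intervals.csv", "birth interval summaries")

        if config.get("standardise") and reference is not None:
            stage = "standardise"
            weighted, _, weights = attach_weights(respondents, relatives, reference, ASSET_ITEMS, seed=seed)
            wres = resolve_dates(weighted, completion)
            wres = filter_death_location_scope(wres, config.get("scope", "in_tigray"))
            wrows = []
            for period in standard_periods():
                r = rate_with_ci(respondents, wres[wres["relation"] == "sibling"], period, (15, 50), None, B=B, seed=seed)
                r.standardised = True
                wrows.append(dataclasses.asdict(r) | {"group": "adults"})
            _write(pd.DataFrame(wrows), out / "estimates_standardised.csv", "standardised estimates")
            _write(weights.table, out / "weights.csv", "post-stratification weights")

        if "migration" in config:
            stage = "sensitivity"
            from kinrates.estimators import rate_from_resolved

            sc = MigrationScenario(
                departure_proportion=float(config["migration"].get("proportion", 0.05)),
                n_simulations=int(config["migration"].get("simulations", 100)),
                seed=seed,
            )
            sims = migration_sensitivity(
                resolved[resolved["relation"] == "sibling"],
                sc,
                lambda r: rate_from_resolved(r, war, (15, 50)).rate_per_1000py,
            )
            _write(sims, out / "migration_sensitivity.csv", "war-period adult rate per simulation")
            summary["migration"] = summarise_migration(sims)

        stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        summary["manifest"] = str(out / "manifest.json")
        return summary
    except Exception as exc:  # noqa: BLE001 — annotate the failing stage
        log.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
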