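"""Attrition, roster and cause-of-death tabulations.

Two inputs: the packaged record-level fixture that transcribes the
published survey's printed aggregates, and the synthetic survey from
01_simulate_survey.py. Writes the eligibility/attrition cascade, the
relation x source x status roster table, and war-period death
cross-tabulations under results/tables/.
"""

from pathlib import Path

from kinrates.exposure import standard_periods
from kinrates.ingest import apply_eligibility, assemble_rosters, completion_series, tabulate_deaths
from kinrates.pipeline import _write, read_table
from kinrates.synthetic import build_paper_fixture

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "tables"
WAR = standard_periods()[-1]


def main() -> None:
    fx = build_paper_fixture()
    rep = apply_eligibility(fx["accesses"])
    _write(rep.table, OUT / "fixture_attrition.csv", "eligibility and attrition cascade")
    print(f"fixture: {rep.counts['all_accesses']} accesses -> {rep.eligible} eligible "
          f"-> {rep.analysable} analysable")

    rs = assemble_rosters(fx["respondents"], fx["relatives"])
    _write(rs.table, OUT / "fixture_roster.csv", "relation x source x status counts")
    comp = completion_series(fx["respondents"])
    t = tabulate_deaths(fx["relatives"], comp, period=WAR)
    _write(t.by_cause.reset_index(names="cause"), OUT / "fixture_war_deaths_by_cause.csv",
           "war-period in-region deaths")
    _write(t.by_zone.reset_index(names="zone"), OUT / "fixture_war_deaths_by_zone.csv",
           "war-period in-region deaths")
    inj = t.by_cause.loc["intentional_injury"]
    print(f"fixture: {t.total} war-period deaths in region, "
          f"{inj['count']} ({inj['pct']}%) from intentional injury")

    syn = ROOT / "results" / "synthetic"
    if (syn / "relatives.csv").exists():
        respondents = read_table(syn / "respondents.csv")
        relatives = read_table(syn / "relatives.csv")
        rs2 = assemble_rosters(respondents, relatives)
        _write(rs2.table, OUT / "synthetic_roster.csv", "relation x source x status counts")
        t2 = tabulate_deaths(relatives, completion_series(respondents), period=WAR)
        _write(t2.by_cause.reset_index(names="cause"), OUT / "synthetic_war_deaths_by_cause.csv",
               "war-period in-region deaths, synthetic survey")
        print(f"synthetic: {t2.total} war-period deaths in region, injury share "
              f"{t2.by_cause.loc['intentional_injury', 'pct']}%")
    else:
        print("synthetic survey not found - run 01_simulate_survey.py first")


if __name__ == "__main__":
    main()
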