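"""Generate the working synthetic survey at the default study conditions.

Writes a 791-respondent diaspora survey (respondents, relatives, reference
sample, ground truth) under results/synthetic/. All downstream analysis
scripts read these files, so the whole analysis is reproducible from one
seed.
"""

from pathlib import Path

from kinrates.config import SimConfig
from kinrates.pipeline import _write
from kinrates.synthetic import generate_reference, generate_survey

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20230418


def main() -> None:
    cfg = SimConfig(seed=SEED)
    respondents, relatives, truth = generate_survey(cfg)
    reference = generate_reference(cfg, 2000)
    _write(respondents, OUT / "respondents.csv", "one row per analysable respondent")
    _write(relatives, OUT / "relatives.csv", "one row per reported relative")
    _write(reference, OUT / "reference.csv", "reference sample: residence + asset items")
    for name, df in truth.items():
        _write(df, OUT / f"truth_{name}.csv", "simulation ground truth (not part of the survey export)")
    n_fam = relatives["family_id"].nunique()
    print(
        f"simulated {len(respondents)} respondents, {n_fam} families, "
        f"{len(relatives)} relatives "
        f"({(relatives['status'] == 'deceased').sum()} deceased, "
        f"{(relatives['status'] == 'unknown').sum()} status-unknown)"
    )


if __name__ == "__main__":
    main()
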