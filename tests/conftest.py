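import pandas as pd
import pytest

from kinrates.config import SimConfig
from kinrates.ingest import completion_series, filter_death_location_scope
from kinrates.exposure import resolve_dates
from kinrates.synthetic import build_paper_fixture, generate_survey


@pytest.fixture(scope="session")
def paper_fixture():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def paper_completion(paper_fixture):
    return completion_series(paper_fixture["respondents"])


@pytest.fixture(scope="session")
def small_survey():
    """A small synthetic survey under default study conditions."""
    cfg = SimConfig(n_respondents=300, seed=5)
    respondents, relatives, truth = generate_survey(cfg)
    return cfg, respondents, relatives, truth


@pytest.fixture(scope="session")
def small_resolved(small_survey):
    _, respondents, relatives, _ = small_survey
    resolved = resolve_dates(relatives, completion_series(respondents))
    return respondents, filter_death_location_scope(resolved)
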