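import numpy as np
import pandas as pd
import pytest

from sedrisk.data_model import SurveyTable
from sedrisk.synthetic import SyntheticConfig, generate_survey


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def default_survey(default_config) -> SurveyTable:
    return generate_survey(default_config, seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231105)


def make_survey(rows) -> SurveyTable:
    """Small helper: rows of (site, season, metal, replicate, value[, censored, lod])."""
    recs = []
    for row in rows:
        site, season, metal, rep, value = row[:5]
        censored = row[5] if len(row) > 5 else False
        lod = row[6] if len(row) > 6 else float("nan")
        recs.append(dict(site=site, season=season, metal=metal, replicate=rep,
                         value=value, censored=censored, lod=lod))
    df = pd.DataFrame(recs)
    return SurveyTable(df, list(dict.fromkeys(df["site"])))
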