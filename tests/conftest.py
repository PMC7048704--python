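import pandas as pd
import pytest

from rmnch import io
from rmnch.synthetic import SurveyConfig, generate_survey


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return io.bundled_table("table1_coverage")


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return io.bundled_table("table2_residence_2016")


@pytest.fixture(scope="session")
def table3() -> pd.DataFrame:
    return io.bundled_table("table3_education_2016")


@pytest.fixture(scope="session")
def gradient_config() -> SurveyConfig:
    return SurveyConfig(
        n_households=3000,
        year=2016,
        seed=42,
        coverage_spec={
            "sba": {
                "poorest": 20,
                "poorer": 35,
                "middle": 50,
                "wealthier": 65,
                "wealthiest": 80,
            },
            "anc_skilled": 70,
            "ort": {
                "poorest": 40,
                "poorer": 50,
                "middle": 60,
                "wealthier": 70,
                "wealthiest": 80,
            },
        },
    )


@pytest.fixture(scope="session")
def gradient_survey(gradient_config):
    return generate_survey(gradient_config)
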