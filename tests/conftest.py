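import numpy as np
import pytest

from eurdtool.registry import SafetyFeatures, SubstanceRecord, SurveyEntry, SurveyTable
from eurdtool.screening import aggregate_survey
from eurdtool.model import fit_log1p_model
from eurdtool.synthetic import GeneratorConfig, generate_features, generate_survey


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(n_substances=60, seed=42)


@pytest.fixture(scope="session")
def feature_frame(small_config):
    return generate_features(small_config)


@pytest.fixture(scope="session")
def survey_table(feature_frame, small_config):
    return generate_survey(feature_frame, small_config)


@pytest.fixture(scope="session")
def fitted_model(feature_frame, survey_table):
    return fit_log1p_model(aggregate_survey(survey_table), feature_frame)


@pytest.fixture
def substance_records() -> list[SubstanceRecord]:
    return [
        SubstanceRecord("S0000", "alpha", 30.0, 13.0, 2025, True, True),
        SubstanceRecord("S0001", "beta", 3.5, 0.5, 2022, False, True),
        SubstanceRecord("S0002", "gamma", 12.0, 3.0, 2023, False, True),
        SubstanceRecord("S0003", "delta", 25.0, 10.0, 2028, False, False),
    ]


@pytest.fixture
def safety_features() -> list[SafetyFeatures]:
    return [
        SafetyFeatures("S0000", 1, 0, 120, 8, 6, 30, 12),
        SafetyFeatures("S0001", 0, 1, 40, 2, 1, 9, 4),
        SafetyFeatures("S0002", 2, 0, 300, 20, 15, 80, 33),
        SafetyFeatures("S0003", 0, 0, 5, 0, 0, 1, 0),
    ]


@pytest.fixture
def tiny_survey() -> SurveyTable:
    return SurveyTable(
        entries=[
            SurveyEntry("S0000", "R00", 4.0),
            SurveyEntry("S0000", "R01", 4.0),
            SurveyEntry("S0000", "R02", 4.0),
            SurveyEntry("S0001", "R00", 2.0),
            SurveyEntry("S0001", "R01", 8.0),
            SurveyEntry("S0002", "R00", 10.0),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
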