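import numpy as np
import pytest

from hazshift.distribution_params import build_survey_age_units
from hazshift.synthetic_data import (
    GeneratorConfig,
    desk_scale_config,
    generate_multisurvey_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """4 countries x 2 surveys x 500 children, default curves."""
    return generate_multisurvey_dataset(desk_scale_config(seed=11))


@pytest.fixture(scope="session")
def small_units(small_dataset):
    records, meta = small_dataset
    return build_survey_age_units(records, meta)


@pytest.fixture(scope="session")
def medium_dataset():
    """20 countries x 2 surveys x 1500 children: enough signal for trend tests."""
    cfg = GeneratorConfig(
        n_countries=20, surveys_per_country=2, children_per_survey=1500, seed=5
    )
    return generate_multisurvey_dataset(cfg)


@pytest.fixture(scope="session")
def medium_units(medium_dataset):
    records, meta = medium_dataset
    return build_survey_age_units(records, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
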