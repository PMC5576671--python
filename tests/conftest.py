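import numpy as np
import pytest

import seastab as st


@pytest.fixture(scope="session")
def default_config() -> st.GeneratorConfig:
    return st.GeneratorConfig.default(seed=7)


@pytest.fixture(scope="session")
def survey(default_config):
    return st.generate_survey(default_config)


@pytest.fixture(scope="session")
def age_rule(default_config) -> st.AgeClassRule:
    return st.AgeClassRule.from_lmax(
        dict(zip(default_config.species, default_config.lmax_cm)))


@pytest.fixture(scope="session")
def transect_table(survey):
    return st.aggregate_density(survey, level="transect")


@pytest.fixture(scope="session")
def site_sum_table(survey):
    return st.aggregate_density(survey, level="site", aggregation="sum")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
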