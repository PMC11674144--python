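import numpy as np
import pytest

import echoedema as ee
from echoedema.pipeline import build_dataset


@pytest.fixture(scope="session")
def default_config():
    return ee.PipelineConfig()


@pytest.fixture(scope="session")
def default_records(default_config):
    return ee.generate_cohort(default_config.cohort)


@pytest.fixture(scope="session")
def default_observations(default_config):
    return ee.generate_infarct_observations(default_config.cohort)


@pytest.fixture(scope="session")
def raw_feature_table(default_records):
    return ee.extract_feature_table(default_records)


@pytest.fixture(scope="session")
def default_dataset(default_config, raw_feature_table, default_observations):
    return build_dataset(default_config, raw_feature_table, default_observations)


@pytest.fixture
def rng():
    # function-scoped: every test sees the same fresh stream regardless of
    # which other tests ran before it
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cohort_config():
    """A fast, small cohort for smoke/CLI tests."""
    return ee.CohortConfig(
        n_subjects=2,
        n_replicates=2,
        record_duration_s=8e-6,
        seed=3,
    )
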