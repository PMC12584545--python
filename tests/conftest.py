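import numpy as np
import pytest

from owclust import SimulationConfig, SurvClust, generate_cohort


@pytest.fixture(scope="session")
def strong_cohort():
    """Default two-subtype cohort with a clear survival-linked signal."""
    return generate_cohort(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def strong_model(strong_cohort):
    return SurvClust(strong_cohort.feature_blocks, strong_cohort.survival)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
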