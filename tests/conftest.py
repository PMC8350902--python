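import numpy as np
import pytest

from taucompare.cohort import (
    GeneratorConfig,
    apply_missingness,
    censor_plasma,
    generate_cohort,
)
from taucompare.impute import ImputationConfig, impute


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(n_participants=400, seed=0)


@pytest.fixture(scope="session")
def cohort(default_config):
    """A complete (no-missingness) default cohort with its ground truth."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def observed_cohort(default_config):
    """The default cohort after censoring and missingness, as analyzed."""
    table, _ = generate_cohort(default_config)
    return apply_missingness(censor_plasma(table, default_config), default_config)


@pytest.fixture(scope="session")
def imputed_set(observed_cohort):
    return impute(observed_cohort, ImputationConfig(m=5, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
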