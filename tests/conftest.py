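import numpy as np
import pytest

from alfnet import default_config, generate_cohort, null_config


@pytest.fixture(scope="session")
def small_cohort():
    """Default-conditions cohort at reduced size, shared across tests."""
    cfg = default_config(seed=11, n_survivors=150, n_nonsurvivors=100)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Both groups drawn from one distribution; no hazard effect."""
    cfg = null_config(seed=7, n_survivors=150, n_nonsurvivors=100)
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
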