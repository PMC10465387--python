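import numpy as np
import pytest

from trimod import simulate
from trimod.io import log2_transform


@pytest.fixture(scope="session")
def small_config():
    """A compact planted cohort used across modules: 120 samples, 3 clusters."""
    return simulate.SimConfig(n_samples=120, n_background_genes=300,
                              n_prognostic_genes=40, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_log2(small_cohort):
    expr, _, _, _ = small_cohort
    return log2_transform(expr)


@pytest.fixture()
def rng():
    return np.random.default_rng(202409)
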