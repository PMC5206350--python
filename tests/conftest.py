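import numpy as np
import pytest

from phytomer import synthetic_data as sd
from phytomer import reconstruction as rc

#: canonical seed for every stochastic fixture
SEED = 0


@pytest.fixture(scope="session")
def default_config():
    return sd.default_config(seed=SEED)


@pytest.fixture(scope="session")
def experiment(default_config):
    """The full study-sized experiment (4 treatments x 2 chambers x 8 tillers)."""
    obs, diss, truth = sd.generate_experiment(default_config)
    return obs, diss, truth


@pytest.fixture(scope="session")
def reconstructed(experiment):
    obs, diss, _ = experiment
    return rc.reconstruct(obs, diss)


@pytest.fixture(scope="session")
def noiseless_config():
    return sd.default_config(seed=SEED).without_noise()


@pytest.fixture(scope="session")
def noiseless_experiment(noiseless_config):
    obs, diss, truth = sd.generate_experiment(noiseless_config)
    return obs, diss, truth


@pytest.fixture(scope="session")
def small_config():
    """One treatment, one chamber, four tillers: fast unit-level runs."""
    cfg = sd.default_config(seed=SEED)
    return sd.GeneratorConfig(
        seed=SEED,
        treatments=(cfg.treatments[0],),
        chambers_per_treatment=1,
        tillers_per_chamber=4,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
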