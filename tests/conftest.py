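import numpy as np
import pytest

from soursim.batch import KineticParams
from soursim.reactions import build_communities
from soursim.synth import default_batch_truth, make_batch_set


@pytest.fixture(scope="session")
def communities():
    return build_communities()


@pytest.fixture(scope="session")
def batch_truth():
    return default_batch_truth()


@pytest.fixture(scope="session")
def srb_network(communities):
    return [communities["SRB"]]


@pytest.fixture(scope="session")
def srb_params():
    return {"SRB": KineticParams(2.0e-6, 1e-4, 2e-4, I=1e-4, b=0.0, X0=2000.0)}


@pytest.fixture(scope="session")
def noiseless_batch_set():
    return make_batch_set(noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def noisy_batch_set():
    return make_batch_set(noise_sigma=0.05, seed=1)


@pytest.fixture
def t_grid_12h():
    return np.linspace(0.0, 12 * 3600.0, 13)
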