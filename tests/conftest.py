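import numpy as np
import pytest

from betamod import EpochedEEG, standard_61_montage
from betamod.simulate import SimScenario


@pytest.fixture(scope="session")
def montage():
    return standard_61_montage()


@pytest.fixture(scope="session")
def small_scenario():
    """Reduced trial count: fast generation, same stated world otherwise."""
    return SimScenario(seed=7, n_trials=40)


def make_epochs(data, montage, fs=256.0):
    n = data.shape[-1]
    times = -0.5 + np.arange(n) / fs
    return EpochedEEG(data, fs, times, montage)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
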