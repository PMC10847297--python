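import numpy as np
import pytest

from dpae.signals import gen_clean_eeg, gen_emg, gen_eog


@pytest.fixture(scope="session")
def eeg100():
    return gen_clean_eeg(100, seed=1)


@pytest.fixture(scope="session")
def eog100():
    return gen_eog(100, seed=1)


@pytest.fixture(scope="session")
def emg100():
    return gen_emg(100, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
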