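import numpy as np
import pytest

from echoroost import DOAModel, PropagationModel, build_arena


@pytest.fixture(scope="session")
def arena():
    return build_arena()


@pytest.fixture(scope="session")
def model():
    return PropagationModel()


@pytest.fixture(scope="session")
def doa_model():
    return DOAModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
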