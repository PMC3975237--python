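import numpy as np
import pytest

from aquamono.model import ModelParams, StatePoint


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def params_q2():
    return ModelParams(q=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def point():
    return StatePoint(T=0.8, P=0.4)
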