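import numpy as np
import pytest

from serpensgate import nn


@pytest.fixture(autouse=True)
def _seed_weights():
    """Deterministic weight initialisation for every test."""
    nn.seed_init(0)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
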