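import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tlsvalid import synthetic

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture
def toy_group():
    return synthetic.toy_chain(20, seed=1)


@pytest.fixture
def motions():
    return synthetic.random_valid_motions(3)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(key=1234))
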