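import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def layout22():
    from blocklik import SampleLayout

    return SampleLayout(sizes=(2, 2), block_length=2000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
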