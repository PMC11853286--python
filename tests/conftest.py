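import numpy as np
import pytest
from hypothesis import settings

from ofcalc import generate_schedule

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def schedule():
    """One fixed default 20-shock schedule shared across tests."""
    return generate_schedule(seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
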