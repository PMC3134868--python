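import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from lipokin import CarrierEnsemble  # noqa: E402


@pytest.fixture
def symmetric_ensemble() -> CarrierEnsemble:
    """100 donors + 100 acceptors, unit volume, capacity 100, no offset."""
    return CarrierEnsemble(n_donor=100, n_acceptor=100, volume=1.0, capacity=100)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
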