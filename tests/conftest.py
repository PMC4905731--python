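import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from salclear.models import EnzymeParams
from salclear.synthetic import DEFAULT_S0, default_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_truth() -> EnzymeParams:
    """Reversible enzyme scheme at the simultaneous-fit reference values."""
    return EnzymeParams.from_affinities(
        KS=10.44, KP=273.5, koff2=14.82, kon1=3.0, ETOT=1.5e-4, S0=DEFAULT_S0["mid"]
    )


@pytest.fixture(scope="session")
def scenario():
    """Default three-dose synthetic scenario (1% proportional noise)."""
    return default_scenario(seed=2015)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
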