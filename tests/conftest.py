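import pytest
from hypothesis import HealthCheck, settings

from clonosim import SimParams, clone_census, grow_to, initialize_tumor

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grown_tumor():
    """A 20k-cell tumor grown from 200 founders (shared, read-only)."""
    params = SimParams(target_size=20_000, rng_seed=11)
    return grow_to(initialize_tumor(200, params), params)


@pytest.fixture(scope="session")
def tumor_census(grown_tumor):
    return clone_census(grown_tumor)


@pytest.fixture(scope="session")
def tumor_profile(tumor_census):
    return tumor_census.to_profile()
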