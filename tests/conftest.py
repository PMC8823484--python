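import pytest
from hypothesis import HealthCheck, settings

import difkit as dk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gds_key():
    return dk.ScaleKey.gds15()


@pytest.fixture(scope="session")
def small_cohort():
    """Two balanced groups, no DIF; shared across read-only tests."""
    spec = dk.make_gds_like(101, group_sizes=(350, 380))
    rm, cov, truth = dk.generate(spec)
    return rm, cov, truth, spec


@pytest.fixture(scope="session")
def dif_cohort():
    """One item with a +0.6 focal difficulty shift (uniform DIF)."""
    spec = dk.make_gds_like(202, group_sizes=(800, 800), dif={4: {"focal": (0.0, 0.6)}})
    rm, cov, truth = dk.generate(spec)
    return rm, cov, truth, spec
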