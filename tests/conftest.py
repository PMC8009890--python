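import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_maps():
    from erpstates import make_maps

    return make_maps(4, 64, max_abs_corr=0.5, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort for pipeline-level tests."""
    from erpstates import SimConfig, simulate_cohort

    cfg = SimConfig(group_sizes=(8, 10, 6), seed=77)
    records, erps, truth, maps = simulate_cohort(cfg)
    return cfg, records, erps, truth, maps
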