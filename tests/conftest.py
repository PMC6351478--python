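import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def default_cohort():
    """One full synthetic cohort at study scale, shared across tests."""
    from mspls import synth

    return synth.generate_cohort(synth.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort configuration for fast structural tests."""
    from mspls import synth

    return synth.CohortConfig(n_voxels=250, seed=11)
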