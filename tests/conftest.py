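import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240629)


@pytest.fixture
def small_cohort_config():
    from clotperv import CohortConfig

    return CohortConfig(n_patients=25, seed=11)
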