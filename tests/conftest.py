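import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def field_dataset():
    """The built-in ten-site field survey with standardized density."""
    from occuscale.data import standardize_covariates
    from occuscale.datasets import field_control_dataset

    return standardize_covariates(field_control_dataset(), ["density"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
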