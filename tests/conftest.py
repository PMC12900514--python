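import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def annotation():
    from polone.annotation import default_annotation

    return default_annotation()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def worked_model():
    """Three-site model with unit dwell times and hazard ln 2: every site has
    termination probability 1/2, so S = (1, 1/2, 1/4), F = 1/8."""
    from polone.model import PauseTerminationModel

    return PauseTerminationModel(np.ones(3), np.log(2.0), 1.0)
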