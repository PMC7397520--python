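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
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def default_phantom():
    """One noiseless default phantom (affected left head at 66.3 etc.)."""
    from hipspect import AnatomyModel, UptakeParams, build_hip_phantom

    return build_hip_phantom(AnatomyModel(), UptakeParams())


@pytest.fixture(scope="session")
def anatomy():
    from hipspect import AnatomyModel

    return AnatomyModel()
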