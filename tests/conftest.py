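import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grey_uniform_3x3():
    return np.full((3, 3, 1), 128, dtype=np.uint8)


@pytest.fixture
def fragile_model():
    from pixelattack import make_toy_classifier

    return make_toy_classifier("fragile_pixel", 2)


@pytest.fixture
def constant_model():
    from pixelattack import make_toy_classifier

    return make_toy_classifier("constant", 3)
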