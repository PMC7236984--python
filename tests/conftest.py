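import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "woodiqa",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("woodiqa")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_texture():
    """A 128x128 wood-like texture shared by read-only tests."""
    from woodiqa import TextureSpec, make_texture

    return make_texture(TextureSpec(width=128, height=128, seed=11))


@pytest.fixture(scope="session")
def reference_set():
    """Ten 96x96 references for layout tests (small for speed)."""
    from woodiqa.synthetic import make_reference_set

    return make_reference_set(5, n=10, size=96)
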