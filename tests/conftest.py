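import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_phantom_spec():
    """A quick phantom on a reduced grid for tests that iterate."""
    from nmseg.phantom import PhantomSpec

    def _make(**kwargs):
        kwargs.setdefault("grid_shape", (64, 64, 12))
        return PhantomSpec(**kwargs)

    return _make
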