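import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic synthetic scene shared across tests."""
    from alsseg.synthetic_data import SceneConfig, generate_scene

    return generate_scene(SceneConfig(seed=7))
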