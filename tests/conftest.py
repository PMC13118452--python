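import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240417)


@pytest.fixture
def small_library():
    from gsltracer.simulate import synth_library

    return synth_library(25, 25, seed=7)


@pytest.fixture
def bundle_dir(tmp_path, small_library):
    from gsltracer.simulate import synth_feature_bundle

    return synth_feature_bundle(small_library, tmp_path / "bundle", seed=7)
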