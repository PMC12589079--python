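import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vqstroke.features import extract_features_table
from vqstroke.synthetic import SyntheticConfig, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small, well-separated phantom dataset shared across tests.

    40/class train, 10/class test at 64x64 with a strong (+80) lesion and mild
    noise, so training tests can learn quickly.
    """
    out = tmp_path_factory.mktemp("phantoms")
    cfg = SyntheticConfig(
        image_size=64,
        n_normal_train=40,
        n_normal_test=10,
        n_stroke_train=40,
        n_stroke_test=10,
        brain_axes=(24.0, 20.0),
        lesion_radius=6.0,
        lesion_delta=80.0,
        noise_sigma=5.0,
        seed=7,
    )
    manifest = generate_dataset(cfg, out)
    return cfg, manifest, out


@pytest.fixture(scope="session")
def small_features(small_dataset):
    _, manifest, out = small_dataset
    return extract_features_table(manifest, out)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
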