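import numpy as np
import pytest

from myoseg import ModelConfig, build_model, make_dataset


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale architecture: every channel count at 1/8 width."""
    return ModelConfig(width_multiplier=0.125)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=0)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """12 synthetic 96x96 histology images with ground truth, 80/20 split."""
    out = tmp_path_factory.mktemp("dataset")
    manifest = make_dataset(
        12, size_range=(96, 96), out_dir=out, seed=7, split_ratio=0.8, mean_fiber_area=1500
    )
    return manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
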