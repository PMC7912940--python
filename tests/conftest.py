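import numpy as np
import pytest

from msbrainseg.phantom import PhantomConfig, generate_dataset, generate_phantom


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Fast phantom configuration for unit tests (96 px, 2 slices/class)."""
    return PhantomConfig(image_size=96, n_per_class=2, seed=7)


@pytest.fixture(scope="session")
def small_records(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def one_record(small_config):
    return generate_phantom(small_config, class_label=2, slice_seed=0)


@pytest.fixture(scope="session")
def texture_cohort():
    """20 slices per class for texture-statistics assertions."""
    cfg = PhantomConfig(image_size=96, n_per_class=20, seed=13)
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
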