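import numpy as np
import pytest

from gliopipe.phantom import PhantomConfig, generate_volume


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Default phantom scaled to 64x64x15 for fast unit tests."""
    return PhantomConfig().scaled(64, 64, slice_count=15, tumorous_slice_range=(4, 10), seed=7)


@pytest.fixture(scope="session")
def small_volume(small_config):
    return generate_volume(small_config)


@pytest.fixture(scope="session")
def suite_volume():
    """One benchmark-scale phantom (96x96) for segmentation-quality tests."""
    cfg = PhantomConfig().scaled(96, 96, slice_count=21, tumorous_slice_range=(5, 15), seed=3)
    return generate_volume(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
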