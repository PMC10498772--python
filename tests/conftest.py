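import numpy as np
import pytest

from pdcnet import ModelConfig, PhantomParams, build_model, generate_batch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """Eight 32x32 phantom pairs: (images (8,1,32,32), masks (8,32,32))."""
    p = PhantomParams(image_size=32, seed=11)
    return generate_batch(p, range(8))


@pytest.fixture(scope="session")
def tiny_dataset(tiny_phantoms):
    """In-memory train/val dataset for quick training smoke tests."""
    x, y = tiny_phantoms
    return {"train": (x[:6], y[:6]), "val": (x[6:], y[6:]), "test": (x[6:], y[6:])}


@pytest.fixture
def small_model():
    return build_model(ModelConfig(depth=2, base_channels=4, seed=3,
                                   dropblock_rate=0.0))
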