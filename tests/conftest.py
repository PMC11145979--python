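import numpy as np
import pytest

from gppwvgg import SyntheticSpec, generate_arrays


@pytest.fixture(scope="session")
def easy_dataset():
    """Shared easy-difficulty synthetic canopy set: 6 classes x 50, 64 px."""
    spec = SyntheticSpec(num_classes=6, n_per_class=50, size=64, seed=1,
                         difficulty="easy")
    X, y = generate_arrays(spec)
    return X, y


@pytest.fixture(scope="session")
def tiny_train_images():
    """64 images at 32 px for trainability checks."""
    spec = SyntheticSpec(num_classes=6, n_per_class=11, size=32, seed=3,
                         difficulty="easy")
    X, y = generate_arrays(spec)
    return X[:64], y[:64]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
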