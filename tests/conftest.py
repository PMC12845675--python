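import numpy as np
import pytest

from mstsefnet import ModelConfig, SyntheticSpec, TrainConfig, generate_dataset
from mstsefnet.synthetic import make_layout


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_model_config():
    """2-class, 3-electrode, 1-second configuration used by training tests."""
    return ModelConfig(n_channels=3, n_samples=250, n_classes=2,
                       pooling=("avg", (5, 5)))


@pytest.fixture(scope="session")
def separable_spec():
    """Strong-ERD 2-class spec: 400 trials over C3/Cz/C4, 1 s epochs."""
    layout = make_layout(1, 1, 10, 40, n_classes=2,
                         channel_names=("C3", "Cz", "C4"))
    return SyntheticSpec(layout=layout, erd_depth=0.8, noise_scale=0.5,
                         window_length=1.0, seed=42)


@pytest.fixture(scope="session")
def separable_dataset(separable_spec):
    return generate_dataset(separable_spec)


@pytest.fixture(scope="session")
def quick_train_config():
    """Short schedule for functional training tests."""
    return TrainConfig(stage1_epochs=3, stage2_max_epochs=5, seed=7, k_folds=2)
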