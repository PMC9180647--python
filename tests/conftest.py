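import numpy as np
import pytest

import grapesense as gs
from grapesense.deep import TrainConfig, build_cnn, train_model


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-sized Vis-NIR synthetic dataset (1071 samples, 80 bands)."""
    return gs.generate_dataset(gs.visnir_config(seed=1))


@pytest.fixture(scope="session")
def prepped(default_dataset):
    """Default dataset after the SG -> SNV preprocessing chain."""
    return gs.preprocess(default_dataset)


@pytest.fixture(scope="session")
def split(prepped):
    return gs.split_dataset(prepped, seed=3)


@pytest.fixture(scope="session")
def trained_cnn(prepped, split):
    """CNN trained at the desk-scale budget (100 epochs, batch 32, lr 1e-3).

    Session-scoped: the same trained network backs the learning-sanity and
    saliency checks.
    """
    net = build_cnn(prepped.n_bands, seed=0)
    result = train_model(net, prepped, split,
                         TrainConfig(epochs=100, batch_size=32,
                                     learning_rate=1e-3, seed=0))
    return net, result


@pytest.fixture()
def small_dataset():
    """A fast 4-class dataset with well-separated classes (120 samples, 40 bands)."""
    cfg = gs.SceneConfig(
        wavelength_grid=np.linspace(476, 890, 40),
        class_counts={"Cabernet": (30, 30, 30, 30)},
        peak_depths=(0.0, 0.1, 0.2, 0.4),
        noise_sd=0.005,
        seed=11,
    )
    return gs.generate_dataset(cfg)
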