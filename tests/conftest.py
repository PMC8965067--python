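import numpy as np
import pytest

from gltm.dataio import Fragment
from gltm.model import GLTMModel, ModelConfig, TrainConfig, train
from gltm.synthetic import MotifTemplate, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fragment():
    return Fragment(id="frag1", sequence="LIVFAGLIVFAGLIVFAGLIVFAGLIVFAGLIVFAGLIVF")


@pytest.fixture
def tiny_config():
    return ModelConfig(k=5, n=3, u=2, d_a=2, alpha=0.1, seed=3)


@pytest.fixture(scope="session")
def toy_dataset():
    """Small separable set: every positive carries a planted GGGGG run."""
    cfg = SimulationConfig(
        n_positive=40,
        n_negative=40,
        seed=11,
        motif_templates=(MotifTemplate("g5", "GGGGG"),),
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def toy_model(toy_dataset):
    """A small model trained to convergence on the separable toy set."""
    mc = ModelConfig(k=5, n=8, u=16, d_a=8, alpha=0.1, seed=0)
    tc = TrainConfig(
        epochs=60, batch_size=32, learning_rate=2e-3, val_fraction=0.0, seed=0
    )
    model, history = train(toy_dataset, mc, tc)
    return model
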