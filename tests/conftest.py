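import numpy as np
import pytest

from smtrace.model import ModelConfig
from smtrace.simulate import SimulatorConfig, generate_dataset
from smtrace.training import pretrain


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """500 mixed traces at T=500 with full ground truth."""
    return generate_dataset(500, SimulatorConfig(n_frames=500), seed=11)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    return ModelConfig(embed_dim=32, n_layers=2, n_heads=4, n_positions=11)


@pytest.fixture(scope="session")
def trained_toy(tiny_model_cfg):
    """A briefly pre-trained small encoder shared by downstream tests."""
    traces = generate_dataset(600, SimulatorConfig(n_frames=500), seed=21)
    result = pretrain(traces, tiny_model_cfg, steps=120, batch_size=60,
                      seed=5, eval_every=0)
    return result
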