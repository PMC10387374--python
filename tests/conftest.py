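import numpy as np
import pytest

from calfads import synth
from calfads.model import ModelConfig, TrainedModel, _init_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_session():
    """A small noisy line-attractor session for unit tests (no training)."""
    system = synth.make_system("line", 3, 8, seed=7)
    data, truth = synth.simulate_session(system, 20, 0.8, 20, seed=7)
    return system, data, truth


def make_untrained_model(n_neurons: int, seed: int = 0, **cfg_overrides) -> TrainedModel:
    """Randomly initialized model (inference machinery without training)."""
    cfg = ModelConfig(
        n_generator_units=cfg_overrides.pop("n_generator_units", 12),
        n_factors=cfg_overrides.pop("n_factors", 4),
        n_input_dims=cfg_overrides.pop("n_input_dims", 1),
        n_encoder_units=cfg_overrides.pop("n_encoder_units", 10),
        n_controller_units=cfg_overrides.pop("n_controller_units", 8),
        seed=seed,
        **cfg_overrides,
    )
    rng = np.random.default_rng(seed)
    params = _init_params(cfg, n_neurons, rng)
    return TrainedModel(
        params=params,
        config=cfg,
        n_neurons=n_neurons,
        data_mean=np.zeros(n_neurons),
        data_std=np.ones(n_neurons),
    )


@pytest.fixture
def untrained_model():
    return make_untrained_model(8)
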