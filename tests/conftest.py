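import numpy as np
import pytest

from popwave import PopulationPETH, TimeGrid, WaveConfig, simulate_wave


@pytest.fixture
def small_grid() -> TimeGrid:
    return TimeGrid(0.0, 100.0, 10.0)


@pytest.fixture
def small_wave() -> PopulationPETH:
    """Compact wave: 12 neurons, 8 conditions, one grid bin of lag per neuron."""
    cfg = WaveConfig(
        n_neurons=12,
        n_conditions=8,
        per_neuron_lag=10.0,
        group_onsets=(((1, 8), 0.0),),
        seed=7,
        grid=TimeGrid(-50.0, 250.0, 10.0),
    )
    return simulate_wave(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
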