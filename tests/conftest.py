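import numpy as np
import pytest

import glynarx as g


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def short_series():
    """A small valid 5-minute series."""
    values = np.array([5.0, 5.5, 6.0, 6.2, 6.0, 5.8, 5.5, 5.2, 5.0, 4.9])
    return g.GlucoseSeries(times=np.arange(10) * 5.0, values=values)


@pytest.fixture(scope="session")
def sinusoid_series():
    """A noiseless glycemia-like sinusoid: period 24 samples, amplitude 3,
    offset 9 mmol/L — well inside network capacity."""
    t = np.arange(900)
    return g.GlucoseSeries(times=t * 5.0, values=9.0 + 3.0 * np.sin(2 * np.pi * t / 24))


@pytest.fixture(scope="session")
def trained_sinusoid(sinusoid_series):
    """One trained model on the sinusoid, shared across tests."""
    windows = g.make_windows(sinusoid_series)
    model = g.init_network(g.ModelConfig(seed=1))
    trained, report = g.train_open_loop(model, windows, g.TrainConfig(seed=1))
    return trained, report, sinusoid_series
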