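import numpy as np
import pytest

from fdscan import simulate as sim


@pytest.fixture(scope="session")
def null_window_stats():
    """500 no-gene-flow 1-kb windows with per-window statistics."""
    model = sim.DemographicModel.background(1.0, 2.0, window_length=1000, rho=0.01)
    return [sim.window_statistics_row(w) for w in sim.simulate_windows(model, 500, seed=101)]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
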