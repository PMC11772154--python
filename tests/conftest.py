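import numpy as np
import pytest

from bogflux import synthetic


@pytest.fixture(scope="session")
def default_bog():
    """Default synthetic bog run (seeded) shared across tests."""
    cfg = synthetic.SimConfig(seed=42)
    df, truth = synthetic.gen_bog_weekly(cfg)
    return cfg, df, truth


@pytest.fixture(scope="session")
def quiet_bog():
    """Noise-free bog with default drought years."""
    cfg = synthetic.SimConfig(seed=3, noise_sd={})
    df, truth = synthetic.gen_bog_weekly(cfg)
    return cfg, df, truth


@pytest.fixture(scope="session")
def logistic_series():
    """Noise-free chaotic logistic map, 500 points."""
    x = np.empty(500)
    x[0] = 0.23
    for t in range(499):
        x[t + 1] = 3.8 * x[t] * (1.0 - x[t])
    return x
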