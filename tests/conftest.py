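import numpy as np
import pytest

from rnadecay import ExpressionTimeSeries, SimulationConfig, generate_dataset


@pytest.fixture
def toy_series():
    """3 genes x 6 time points, strictly positive raw values."""
    rng = np.random.default_rng(7)
    times = np.array([0.0, 30.0, 60.0, 90.0, 120.0, 150.0])
    values = rng.uniform(1.0, 10.0, size=(3, 6))
    return ExpressionTimeSeries(["geneA", "geneB", "geneC"], times, values)


@pytest.fixture(scope="session")
def noisefree_dataset():
    """Small clean simulated dataset with dense sampling."""
    return generate_dataset(SimulationConfig(m=4, n_times=50, noise=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Moderate-noise simulated dataset at the short-time-course design."""
    return generate_dataset(SimulationConfig(m=30, n_times=6, noise=0.2, seed=5))
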