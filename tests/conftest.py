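import numpy as np
import pytest

from freeknot import ModelData, SimConfig, TrueModel, simulate_dataset


@pytest.fixture(scope="session")
def bmi_dataset():
    """One moderate simulated dataset from the U-shaped true model."""
    rng = np.random.default_rng(20140929)
    data, model = simulate_dataset(SimConfig(n=2000, p0=0.33), rng)
    return data, model


@pytest.fixture(scope="session")
def small_dataset():
    """A 200-point dataset for optimizer cross-checks."""
    rng = np.random.default_rng(7)
    data, model = simulate_dataset(SimConfig(n=200, p0=0.33), rng)
    return data, model


@pytest.fixture()
def flat_logistic_data():
    """Data from a plain (no-knot) logistic model: true K = 0."""
    rng = np.random.default_rng(11)
    model = TrueModel(knots=(), slopes=(0.05,))
    data, m = simulate_dataset(SimConfig(n=500, p0=0.33), rng, model=model)
    return data, m
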