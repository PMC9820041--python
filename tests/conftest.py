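import numpy as np
import pytest

from activitygrid import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A compact deterministic scenario shared by read-only tests."""
    return generate_scenario(ScenarioConfig(n_rows=10, n_cols=10, seed=42))


@pytest.fixture(scope="session")
def noiseless_scenario():
    """Same grid with noise_sd=0: realized rates equal planted rates."""
    return generate_scenario(
        ScenarioConfig(n_rows=10, n_cols=10, seed=42, noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
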