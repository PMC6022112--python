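import numpy as np
import pytest

from nirwood.synthetic import SyntheticConfig, default_config, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One 125 x 117 draw from the reference study conditions."""
    return generate_dataset(default_config(seed=42))


@pytest.fixture(scope="session")
def noiseless_config():
    """Purely linear, scatter/drift/noise-free conditions."""
    return SyntheticConfig(
        seed=7,
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        drift_amplitude=0.0,
        noise_sd=0.0,
        response_noise_sd=0.0,
        nonlinearity_weight=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return generate_dataset(noiseless_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
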