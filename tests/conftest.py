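import numpy as np
import pytest

from specfe import GeneratorConfig, generate_dataset, spxy_split


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_dataset():
    """The standard study-condition dataset: 116 samples, 221 wavelengths."""
    return generate_dataset(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def quiet_dataset():
    """Structured disturbances (scatter gain, drift) off; noise floor kept."""
    return generate_dataset(
        GeneratorConfig(seed=11, gain_sd=0.0, drift_slope_sd=0.0, drift_offset_sd=0.0)
    )


@pytest.fixture(scope="session")
def default_split(default_dataset):
    return spxy_split(default_dataset.reflectance, default_dataset.ssc)
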