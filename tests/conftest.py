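import numpy as np
import pytest

from tanninspec import GeneratorConfig, average_replicates, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_samples=24, n_bands=150, replicates_per_sample=3, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_samples(small_dataset):
    scans, tannins = small_dataset
    return average_replicates(scans), tannins


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
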