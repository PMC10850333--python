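import numpy as np
import pytest

from nirimpurity.spectra_io import SpectraSet
from nirimpurity.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_set(rng):
    """A tiny valid SpectraSet (5 samples x 10 channels)."""
    return SpectraSet(
        wavelengths=np.linspace(950, 1650, 10),
        reflectance=rng.uniform(0.2, 0.9, size=(5, 10)),
        target=rng.uniform(0.03, 0.2, size=5),
        sample_ids=tuple(f"s{i}" for i in range(5)),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default-config synthetic dataset (230 x 125), shared across tests."""
    data, truth = generate_dataset(SyntheticConfig(seed=7))
    return data, truth


@pytest.fixture(scope="session")
def noiseless_dataset():
    data, truth = generate_dataset(
        SyntheticConfig(seed=11, scatter_sd=0.0, baseline_sd=0.0, noise_sd=0.0)
    )
    return data, truth
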