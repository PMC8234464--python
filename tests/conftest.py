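import numpy as np
import pytest

from navpop.channel_core import FactorVector, transform_factors
from navpop.synthetic_data import generate_dataset, reduced_truth


@pytest.fixture(scope="session")
def default_factors():
    return FactorVector.default()


@pytest.fixture(scope="session")
def default_params(default_factors):
    return transform_factors(default_factors)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_dataset():
    """3-paper / 9-experiment synthetic dataset with its generating truth."""
    truth = reduced_truth(seed=7)
    ds, latents = generate_dataset(truth)
    return truth, ds, latents
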