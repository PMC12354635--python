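import numpy as np
import pytest

from danioscope.phenotypes import PhenotypeClass
from danioscope.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Ten 64-px images per class, shared across tests (read-only)."""
    return generate_dataset({c: 10 for c in PhenotypeClass}, image_size=64, seed=99)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
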