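import numpy as np
import pytest

from jeli.datasets import make_synthetic_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small first-order dataset for fast training/evaluation tests."""
    return make_synthetic_dataset(F=6, d=2, n_i=40, n_u=40, sparsity=0.5, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
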