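import numpy as np
import pytest

from neurofuzzy.datasets import (GeneratorSpec, generate, make_breast_cancer_like,
                                 make_separable, worked_example_fixtures)


@pytest.fixture(scope="session")
def fixtures():
    return worked_example_fixtures()


@pytest.fixture(scope="session")
def separable_dataset():
    """Two 2-feature Gaussian classes 6 pooled stds apart, n = 500."""
    return make_separable(n=500, n_features=2, separation=6.0, seed=11)


@pytest.fixture(scope="session")
def breast_like_dataset():
    return make_breast_cancer_like(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
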