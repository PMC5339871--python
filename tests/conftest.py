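import numpy as np
import pytest

from radnet import synthetic


@pytest.fixture(scope="session")
def cohort40():
    """Desk-scale recovery cohort: 500 genes x 40 samples, five 50-gene modules."""
    return synthetic.generate_cohort(n_samples=40, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
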