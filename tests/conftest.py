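import numpy as np
import pytest

from frailbn.reference import build_reference_network
from frailbn.synthetic import sample_cohort


@pytest.fixture(scope="session")
def reference():
    return build_reference_network()


@pytest.fixture(scope="session")
def cohort680(reference):
    return sample_cohort(reference, 680, seed=1)


@pytest.fixture(scope="session")
def cohort20k(reference):
    return sample_cohort(reference, 20_000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
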