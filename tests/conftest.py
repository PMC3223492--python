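import numpy as np
import pytest

import alnbench as ab


@pytest.fixture(scope="session")
def model():
    return ab.dayhoff_model()


@pytest.fixture(scope="session")
def pam250():
    return ab.load_matrix("PAM250")


@pytest.fixture(scope="session")
def gonnet250():
    return ab.load_matrix("Gonnet250")


@pytest.fixture(scope="session")
def global_gap():
    return ab.GapPenalty(14.0, 2.0)


@pytest.fixture(scope="session")
def local_gap():
    return ab.GapPenalty(10.0, 0.5)


@pytest.fixture(scope="session")
def small_set(model):
    """A small diverging-scheme test set at moderate distance."""
    return ab.generate_test_set(ab.EvolParams(pam=30), ab.ConsoleSpec(r=0.1, c=0.1),
                                model, n_pairs=30, seed=123)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987)
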