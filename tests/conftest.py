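import numpy as np
import pytest

from stsclades import load_jtt, load_reference, make_clade_benchmark


@pytest.fixture(scope="session")
def db():
    return load_reference()


@pytest.fixture(scope="session")
def jtt():
    return load_jtt()


@pytest.fixture(scope="session")
def bench():
    """Default synthetic benchmark, fixed seed shared across tests."""
    return make_clade_benchmark(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
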