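import numpy as np
import pytest

from densitree.synthetic_data import generate_fixture_suite

SUITE_SEED = 0


@pytest.fixture(scope="session")
def fixtures():
    """The named small datasets shared across the test modules."""
    return generate_fixture_suite(SUITE_SEED)


@pytest.fixture(scope="session")
def three_branch_2d(fixtures):
    return fixtures["three_branch_2d"]


@pytest.fixture(scope="session")
def two_clusters(fixtures):
    return fixtures["two_clusters"]


@pytest.fixture(scope="session")
def rank2_linear(fixtures):
    return fixtures["rank2_linear"][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
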