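import pytest

from commflux import EQUAL, FREE, build_community
from commflux import fixtures as fx


@pytest.fixture(scope="session")
def toy_pair():
    return fx.make_toy_pair()


@pytest.fixture(scope="session")
def helper():
    return fx.make_helper_strain()


@pytest.fixture(scope="session")
def media():
    return fx.toy_media()


@pytest.fixture(scope="session")
def pair_free(toy_pair):
    A, B, _ = toy_pair
    return build_community([A, B], FREE)


@pytest.fixture(scope="session")
def pair_equal(toy_pair):
    A, B, _ = toy_pair
    return build_community([A, B], EQUAL)


@pytest.fixture(scope="session")
def trio_free(toy_pair, helper):
    A, B, _ = toy_pair
    C, _ = helper
    return build_community([A, B, C], FREE)
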