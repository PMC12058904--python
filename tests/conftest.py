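import pytest

from arcnets import census


@pytest.fixture(scope="session")
def census41():
    return census.run_census(4, 1)


@pytest.fixture(scope="session")
def census42():
    return census.run_census(4, 2)


@pytest.fixture(scope="session")
def census51():
    return census.run_census(5, 1)


@pytest.fixture(scope="session")
def census52():
    # the largest exhaustive run: 623,700 decorated trees
    return census.run_census(5, 2)


@pytest.fixture(scope="session")
def small_censuses(census41, census42, census51):
    """Censuses of the fast exhaustive range, keyed by (n, k)."""
    out = {(4, 1): census41, (4, 2): census42, (5, 1): census51}
    for nk in [(2, 1), (3, 1), (3, 2)]:
        out[nk] = census.run_census(*nk)
    return out
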