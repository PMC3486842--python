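import pytest

from catapot.fixtures import FixtureSpec, make_catalog, planted_model


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def fixture_world(spec):
    """Shared toy catalog, pathway table and organism panel."""
    return make_catalog(spec)


@pytest.fixture(scope="session")
def catalog(fixture_world):
    return fixture_world[0]


@pytest.fixture(scope="session")
def pathway_catalog(fixture_world):
    return fixture_world[1]


@pytest.fixture(scope="session")
def organisms(fixture_world):
    return {org.id: org for org in fixture_world[2]}


@pytest.fixture(scope="session")
def logistic_model(spec):
    return planted_model(spec)
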