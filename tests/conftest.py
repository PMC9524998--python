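import pytest

from medna.store import Store
from medna.synth import FixtureSpec, generate_fixture
from medna.vocab import load_defaults


@pytest.fixture(scope="session")
def registry():
    return load_defaults()


@pytest.fixture()
def store(registry):
    return Store(registry=registry.clone())


@pytest.fixture(scope="session")
def fixture_store():
    """The standard defect-free fixture (seed 7, 2 sites, 2 surveys, 3 samples)."""
    return generate_fixture(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def defect_store():
    return generate_fixture(FixtureSpec(seed=7, defect_rate=0.5))
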