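import pytest

from fmdd import toy_network
from fmdd.dopamine import load_dopamine_model
from fmdd.fixtures import FixtureSpec, generate_random_gma


@pytest.fixture()
def toy():
    return toy_network()


@pytest.fixture(scope="session")
def dopamine_net():
    return load_dopamine_model()


@pytest.fixture(scope="session")
def random_nets():
    """A small bank of random consistent networks of varied dimensions."""
    specs = [
        FixtureSpec(n_species=4, n_reactions=7, n_controls=0, seed=11),
        FixtureSpec(n_species=6, n_reactions=10, n_controls=1, seed=5),
        FixtureSpec(n_species=8, n_reactions=14, n_controls=2, seed=23),
    ]
    return [generate_random_gma(s) for s in specs]
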