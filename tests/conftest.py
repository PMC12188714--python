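import pytest

from oxevo import screen, synth


@pytest.fixture(scope="session")
def catalog():
    return screen.PathwayCatalog.default()


@pytest.fixture(scope="session")
def scg_reference():
    return screen.single_copy_reference()


@pytest.fixture(scope="session")
def taxonomy_tree():
    """16-species, 4-phylum ultrametric taxonomy used across modules."""
    return synth.simulate_taxonomy(16, 4, seed=1)
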