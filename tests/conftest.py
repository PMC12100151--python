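import pytest

from tandemtally.constructs import (
    default_background_pool,
    default_plasmid_map,
    small_plasmid_map,
)


@pytest.fixture(scope="session")
def default_map():
    """Full-scale synthetic construct: 5.8 kb vector, 2 kb repeat unit."""
    return default_plasmid_map()


@pytest.fixture(scope="session")
def small_map():
    """Miniature construct (1.4 kb vector, 250 bp unit) for quadratic-time
    cross-checks."""
    return small_plasmid_map()


@pytest.fixture(scope="session")
def background_pool():
    return default_background_pool()
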