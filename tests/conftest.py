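from pathlib import Path

import pytest

from phylofidelity import (
    make_tree_set,
    patristic_distances,
    read_newick,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_tree():
    """((A:1,B:1):1,C:2); — the 3-tip chronogram used for hand computations."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def toy_dist(toy_tree):
    return patristic_distances(toy_tree)


@pytest.fixture(scope="session")
def oracle_tree():
    return read_newick((DATA / "oracle_tree.nwk").read_text())


@pytest.fixture(scope="session")
def small_quintet():
    """An 80-tip tree quintet under the default degradation settings."""
    return make_tree_set(80, 100.0, seed=424)
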