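"""Shared fixtures: small hand-checkable graphs and a fast walk config."""

import pytest

from linkbench.embedding import WalkConfig
from linkbench.graph_io import TemporalGraph


@pytest.fixture
def path_graph():
    """a - b - c"""
    return TemporalGraph.from_links([("a", "b"), ("b", "c")])


@pytest.fixture
def triangle():
    return TemporalGraph.from_links([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def bipartite_dti():
    """Drugs {d1, d2} x targets {t1, t2} with links d1-t1, d2-t1, d2-t2."""
    from linkbench.graph_io import attach_partition

    g = TemporalGraph.from_links([("d1", "t1"), ("d2", "t1"), ("d2", "t2")])
    return attach_partition(g, {"d1": "A", "d2": "A", "t1": "B", "t2": "B"})


@pytest.fixture
def dated_graph():
    """Four links dated 1990/2000/2010/2020 over five nodes."""
    links = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
    years = {("a", "b"): 1990, ("b", "c"): 2000, ("c", "d"): 2010, ("d", "e"): 2020}
    return TemporalGraph.from_links(links, year=years)


@pytest.fixture
def fast_walk_cfg():
    """Small dimensions/corpus for unit tests that only need the contract."""
    return WalkConfig(walk_length=10, walks_per_vertex=5, window=4,
                      dimensions=16, epochs=2, seed=0)
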