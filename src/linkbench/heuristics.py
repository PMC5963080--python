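"""Neighbourhood-overlap link-prediction heuristics.

Three classical scores over the induction graph's neighbour sets N(u),
N(v): Common Neighbours ``|N(u) ∩ N(v)|``, a common-neighbour-count
Adamic-Adar variant ``1/log|N(u) ∩ N(v)|``, and the Jaccard index
``|N(u) ∩ N(v)| / |N(u) ∪ N(v)|``.

On a bipartite graph two linkable nodes never share direct neighbours, so
the second argument's neighbourhood is replaced by its two-hop
neighbourhood N̂(v) = ∪_{w∈N(v)} N(w) (a deduplicated set, which may
contain v itself). The A-partition node is always passed first, making the
asymmetric bipartite forms deterministic.

Adamic-Adar degenerate counts: the reciprocal-log form is undefined at
c=1 (log 1 = 0) and c=0. c=0 scores 0 (no shared evidence); c=1 scores a
finite cap of 2/ln 2, chosen strictly above the c=2 score so the score
remains strictly decreasing in c — the ordering principle the heuristic
encodes (few shared items weigh more than many).
"""

from __future__ import annotations

import math
from typing import Sequence

from .graph_io import Pair, TemporalGraph
from .ranking import ScoredRanking

METHODS = ("CN", "AA", "JI")

#: score assigned to a single common neighbour; strictly above 1/ln 2 is
#: wrong direction — it must exceed the c=2 score 1/ln 2 ≈ 1.4427, and
#: 2/ln 2 ≈ 2.885 does while staying finite.
AA_SINGLE_NEIGHBOUR_CAP = 2.0 / math.log(2.0)


def _check(g: TemporalGraph, u: str, v: str) -> None:
    if u not in g.nodes:
        raise KeyError(f"unknown node {u!r}")
    if v not in g.nodes:
        raise KeyError(f"unknown node {v!r}")
    if u == v:
        raise ValueError("heuristics are undefined for self-pairs")


def two_hop_neighbourhood(g: TemporalGraph, v: str) -> set[str]:
    """N̂(v): the set of neighbours of neighbours of v (may include v)."""
    out: set[str] = set()
    for w in g.adjacency[v]:
        out |= g.adjacency[w]
    return out


def _neighbour_sets(g: TemporalGraph, u: str, v: str, bipartite: bool) -> tuple[set, set]:
    nu = g.adjacency[u]
    nv = two_hop_neighbourhood(g, v) if bipartite else g.adjacency[v]
    return nu, nv


def common_neighbours(g: TemporalGraph, u: str, v: str, bipartite: bool = False) -> int:
    """|N(u) ∩ N(v)|, or |N(u) ∩ N̂(v)| on bipartite graphs."""
    _check(g, u, v)
    nu, nv = _neighbour_sets(g, u, v, bipartite)
    return len(nu & nv)


def adamic_adar(g: TemporalGraph, u: str, v: str, bipartite: bool = False) -> float:
    c = common_neighbours(g, u, v, bipartite=bipartite)
    if c == 0:
        return 0.0
    if c == 1:
        return AA_SINGLE_NEIGHBOUR_CAP
    return 1.0 / math.log(c)


def jaccard(g: TemporalGraph, u: str, v: str, bipartite: bool = False) -> float:
    _check(g, u, v)
    nu, nv = _neighbour_sets(g, u, v, bipartite)
    union = len(nu | nv)
    if union == 0:
        return 0.0
    return len(nu & nv) / union


_SCORERS = {"CN": common_neighbours, "AA": adamic_adar, "JI": jaccard}


def score_pair(g: TemporalGraph, u: str, v: str, method: str, bipartite: bool = False) -> float:
    if method not in _SCORERS:
        raise ValueError(f"unknown heuristic {method!r}; choose from {METHODS}")
    return float(_SCORERS[method](g, u, v, bipartite=bipartite))


def score_all(
    g: TemporalGraph,
    pairs: Sequence[Pair],
    method: str,
    labels: Sequence[int] | None = None,
    bipartite: bool | None = None,
) -> ScoredRanking:
    """Score a batch of candidate pairs and return the sorted ranking.

    ``bipartite`` defaults to whether the graph carries a partition. Pairs
    are assumed canonically ordered (A-side first on bipartite graphs).
    """
    if bipartite is None:
        bipartite = g.partition is not None
    if labels is None:
        labels = [0] * len(pairs)
    scores = [score_pair(g, u, v, method, bipartite=bipartite) for u, v in pairs]
    return ScoredRanking.from_scores(pairs, scores, labels, method=method)
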