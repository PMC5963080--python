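"""No-common-neighbour diagnostic.

Links that form between nodes sharing no prior common neighbour are
invisible to neighbourhood-overlap heuristics — Common Neighbours scores
them exactly 0 — yet they are arguably the most interesting predictions
(unexpected interactions, cross-community discoveries). This module
quantifies such test positives and asks, per scoring method, what fraction
of them lands in the top half of the full ranked list. With 1:1 negatives
a good predictor should place most true links in the top half, so this
fraction isolates where a method's ranking skill comes from.

Because all no-common-neighbour links tie at score 0 under the CN
heuristic, their top/bottom-half placement depends on tie handling; the
deterministic lexicographic placement is reported alongside the expected
value under random tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph_io import Pair, TemporalGraph
from .heuristics import common_neighbours
from .ranking import ScoredRanking


def find_no_cn_positives(
    induction: TemporalGraph, test_pos: set[Pair], bipartite: bool = False
) -> set[Pair]:
    """Test positives whose endpoints share no common neighbour in the
    induction graph (bipartite variant when flagged).

    Endpoints absent from the induction graph have empty neighbourhoods,
    hence trivially no common neighbours — those links are included.
    """
    out: set[Pair] = set()
    for u, v in test_pos:
        if u not in induction.nodes or v not in induction.nodes:
            out.add((u, v))
        elif common_neighbours(induction, u, v, bipartite=bipartite) == 0:
            out.add((u, v))
    return out


def top_half_fraction(r: ScoredRanking, subset: set[Pair]) -> float:
    """Fraction of ``subset`` ranked within the top floor(n/2) entries."""
    if len(r) == 0:
        raise ValueError("empty ranking")
    positions = {e.pair: i for i, e in enumerate(r.entries, start=1)}
    missing = subset - positions.keys()
    if missing:
        raise KeyError(f"{len(missing)} subset pair(s) absent from ranking, "
                       f"e.g. {next(iter(missing))}")
    if not subset:
        return 0.0
    half = len(r) // 2
    return sum(1 for p in subset if positions[p] <= half) / len(subset)


def top_half_fraction_random_ties(r: ScoredRanking, subset: set[Pair]) -> float:
    """Expected top-half fraction if ties were broken uniformly at random.

    For each subset pair, the probability of landing in the top half given
    its tie group's rank span: 1 if the whole group is above the midpoint,
    0 if below, else the fraction of the group's span above it.
    """
    if len(r) == 0:
        raise ValueError("empty ranking")
    if not subset:
        return 0.0
    half = len(r) // 2
    # rank span per score value
    spans: dict[float, tuple[int, int]] = {}
    start = 1
    i = 0
    entries = r.entries
    while i < len(entries):
        j = i
        while j < len(entries) and entries[j].score == entries[i].score:
            j += 1
        spans[entries[i].score] = (i + 1, j)  # 1-based inclusive span
        i = j
    by_pair = {e.pair: e.score for e in entries}
    missing = subset - by_pair.keys()
    if missing:
        raise KeyError(f"{len(missing)} subset pair(s) absent from ranking")
    total = 0.0
    for p in subset:
        lo, hi = spans[by_pair[p]]
        if hi <= half:
            total += 1.0
        elif lo > half:
            total += 0.0
        else:
            total += (half - lo + 1) / (hi - lo + 1)
    return total / len(subset)


@dataclass
class NoCnReport:
    """Counts of no-common-neighbour test positives and per-method placement."""

    n_test_pos: int
    n_no_cn: int
    per_method: dict[str, float] = field(default_factory=dict)
    per_method_random_ties: dict[str, float] = field(default_factory=dict)

    @property
    def frac_no_cn(self) -> float:
        return self.n_no_cn / self.n_test_pos if self.n_test_pos else 0.0

    def to_tsv(self) -> str:
        lines = ["method\ttop_half_fraction\ttop_half_fraction_random_ties"]
        for method in sorted(self.per_method):
            lines.append(
                f"{method}\t{self.per_method[method]:.4f}"
                f"\t{self.per_method_random_ties[method]:.4f}"
            )
        return "\n".join(lines)


def no_cn_report(
    induction: TemporalGraph,
    test_pos: set[Pair],
    rankings: dict[str, ScoredRanking],
    bipartite: bool = False,
) -> NoCnReport:
    """Full diagnostic: fraction of no-CN positives plus per-method placement."""
    subset = find_no_cn_positives(induction, test_pos, bipartite=bipartite)
    report = NoCnReport(n_test_pos=len(test_pos), n_no_cn=len(subset))
    for method, r in rankings.items():
        report.per_method[method] = top_half_fraction(r, subset)
        report.per_method_random_ties[method] = top_half_fraction_random_ties(r, subset)
    return report
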