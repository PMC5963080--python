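"""Graph container and edge-list I/O.

Graphs are undirected and simple: a link is an unordered pair of distinct
node-ids, optionally carrying an integer year (the year the link formed,
e.g. the publication year of the first co-occurrence) and optionally a
two-way partition of the nodes (drug/target-style bipartite topology).

Node-ids are opaque strings; heterogeneous identifier schemes (database
accessions, concept ids) are never coerced to numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def canonical_pair(u: str, v: str, partition: Mapping[str, str] | None = None) -> Pair:
    """Return the canonical ordering of an unordered node pair.

    Lexicographic by node-id; under a bipartite partition the A-side node
    comes first so that asymmetric bipartite heuristics receive arguments
    in a fixed, reproducible order.
    """
    if u == v:
        raise ValueError(f"self-pair ({u!r}, {u!r}) has no canonical form")
    if partition is not None:
        pu, pv = partition.get(u), partition.get(v)
        if pu == "A" and pv == "B":
            return (u, v)
        if pu == "B" and pv == "A":
            return (v, u)
    return (u, v) if u < v else (v, u)


@dataclass
class TemporalGraph:
    """Undirected simple graph with optional per-link years and bipartition.

    Invariants (checked by :meth:`validate`): links are canonical unordered
    pairs of distinct nodes, endpoints are registered nodes, a partition (if
    present) makes every link cross-partition, and a year map (if present)
    covers every link exactly.
    """

    nodes: set[str] = field(default_factory=set)
    links: set[Pair] = field(default_factory=set)
    year: dict[Pair, int] | None = None
    partition: dict[str, str] | None = None

    _adj: dict[str, set[str]] | None = field(default=None, repr=False, compare=False)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_links(
        cls,
        links: Iterable[Pair],
        nodes: Iterable[str] | None = None,
        year: Mapping[Pair, int] | None = None,
        partition: Mapping[str, str] | None = None,
    ) -> "TemporalGraph":
        part = dict(partition) if partition is not None else None
        canon = {canonical_pair(u, v, part) for u, v in links}
        node_set = set(nodes) if nodes is not None else set()
        for u, v in canon:
            node_set.add(u)
            node_set.add(v)
        year_map = None
        if year is not None:
            year_map = {canonical_pair(u, v, part): y for (u, v), y in year.items()}
        g = cls(nodes=node_set, links=canon, year=year_map, partition=part)
        g.validate()
        return g

    def validate(self) -> None:
        for u, v in self.links:
            if u == v:
                raise ValueError(f"self-link on {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"link ({u!r}, {v!r}) has unregistered endpoint")
            if canonical_pair(u, v, self.partition) != (u, v):
                raise ValueError(f"link ({u!r}, {v!r}) not canonically ordered")
        if self.partition is not None:
            for u, v in self.links:
                pu, pv = self.partition.get(u), self.partition.get(v)
                if pu is None or pv is None:
                    raise ValueError(f"link ({u!r}, {v!r}) has unlabelled endpoint")
                if pu == pv:
                    raise ValueError(
                        f"intra-partition link ({u!r}, {v!r}): both in {pu}"
                    )
        if self.year is not None:
            missing = self.links - self.year.keys()
            if missing:
                raise ValueError(f"{len(missing)} links lack a year, e.g. {next(iter(missing))}")
            extra = self.year.keys() - self.links
            if extra:
                raise ValueError(f"year map covers {len(extra)} non-links")

    # -- queries -----------------------------------------------------------

    @property
    def adjacency(self) -> dict[str, set[str]]:
        if self._adj is None:
            adj: dict[str, set[str]] = {n: set() for n in self.nodes}
            for u, v in self.links:
                adj[u].add(v)
                adj[v].add(u)
            self._adj = adj
        return self._adj

    def neighbours(self, u: str) -> set[str]:
        """Nodes sharing a link with ``u``; never contains ``u`` itself."""
        if u not in self.nodes:
            raise KeyError(f"unknown node {u!r}")
        return set(self.adjacency[u])

    def has_link(self, u: str, v: str) -> bool:
        if u == v:
            return False
        return canonical_pair(u, v, self.partition) in self.links

    def subgraph_of_links(
        self, links: Iterable[Pair], keep_all_nodes: bool = False
    ) -> "TemporalGraph":
        """Graph induced by a link subset.

        With ``keep_all_nodes`` the full node set is retained, so nodes
        whose links all fall outside the subset become isolated nodes
        (with empty neighbourhoods) rather than disappearing — the state a
        link predictor sees for entities that only appear in later slices.
        """
        links = set(links)
        year = {l: self.year[l] for l in links} if self.year is not None else None
        part = dict(self.partition) if self.partition is not None else None
        nodes = set(self.nodes) if keep_all_nodes else None
        return TemporalGraph.from_links(links, nodes=nodes, year=year, partition=part)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.links)
        return g


def neighbours(g: TemporalGraph, u: str) -> set[str]:
    return g.neighbours(u)


# -- edge-list format ------------------------------------------------------
#
#   <u> <v> [<year>]     one link per line, any-whitespace separated
#   # comment            lines starting with '#' are ignored


def sniff_year_column(path) -> bool:
    """True if the first data line of an edge-list file has a year field."""
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            return len(line.split()) == 3
    return False


def read_edge_list(path, has_year: bool = False) -> TemporalGraph:
    """Read a whitespace-delimited edge list into a :class:`TemporalGraph`.

    Duplicate lines collapse to one link; when duplicate observations carry
    conflicting years the earliest is kept (a link "forms" at its first
    observation). Self-links are dropped and counted in the log.
    """
    nodes: set[str] = set()
    links: set[Pair] = set()
    year: dict[Pair, int] = {}
    n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            want = 3 if has_year else 2
            if len(fields) != want:
                raise ValueError(
                    f"{path}:{lineno}: expected {want} fields, got {len(fields)}: {line!r}"
                )
            u, v = fields[0], fields[1]
            nodes.add(u)
            nodes.add(v)
            if u == v:
                n_self += 1
                continue
            pair = canonical_pair(u, v)
            links.add(pair)
            if has_year:
                try:
                    y = int(fields[2])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: year {fields[2]!r} is not an integer")
                year[pair] = min(y, year.get(pair, y))
    if n_self:
        logger.info("read_edge_list(%s): dropped %d self-link(s)", path, n_self)
    g = TemporalGraph(nodes=nodes, links=links, year=year if has_year else None)
    g.validate()
    return g


def write_edge_list(g: TemporalGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(g.links):
            if g.year is not None:
                fh.write(f"{u}\t{v}\t{g.year[(u, v)]}\n")
            else:
                fh.write(f"{u}\t{v}\n")
    # the format carries links only; isolated nodes are not preserved


def read_partition(path) -> dict[str, str]:
    """Read a ``<node-id> <A|B>`` per line partition file."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2 or fields[1] not in ("A", "B"):
                raise ValueError(f"{path}:{lineno}: expected '<node> <A|B>', got {line!r}")
            labels[fields[0]] = fields[1]
    return labels


def write_partition(labels: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for node in sorted(labels):
            fh.write(f"{node}\t{labels[node]}\n")


def attach_partition(g: TemporalGraph, labels: Mapping[str, str]) -> TemporalGraph:
    """Return ``g`` with a two-way partition attached.

    Every node must be labelled A or B and every link must cross the
    partition; an intra-partition link raises naming the offending link.
    """
    unlabelled = g.nodes - labels.keys()
    if unlabelled:
        raise ValueError(f"{len(unlabelled)} unlabelled node(s), e.g. {sorted(unlabelled)[0]!r}")
    bad = {lab for lab in labels.values() if lab not in ("A", "B")}
    if bad:
        raise ValueError(f"labels must be 'A' or 'B', got {sorted(bad)}")
    part = {n: labels[n] for n in g.nodes}
    for u, v in g.links:
        if part[u] == part[v]:
            raise ValueError(
                f"bipartiteness violated: link ({u!r}, {v!r}) joins two {part[u]} nodes"
            )
    return TemporalGraph.from_links(g.links, nodes=g.nodes, year=g.year, partition=part)
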