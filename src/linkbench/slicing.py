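"""Induction/train/test splits and negative sampling.

Two slicing regimes:

* **random-slice** — links are removed uniformly at random into the test
  set while preserving the connectivity of every component of the input
  graph; a fraction of the remaining (induction) links doubles as the
  predictor's training positives, since representations are built from all
  induction links anyway.
* **time-slice** — links are assigned to slices by formation year: the
  induction window up to a cut year, a training window at the end of the
  induction era, and a test window after the cut. Connectivity cannot be
  enforced here; nodes whose first link falls after the cut enter the test
  era with no representation.

Negatives are unlinked node pairs sampled uniformly, 1:1 with positives,
excluded against the positives of the *full* graph so no test positive can
double as a negative. Under a bipartition only cross-partition pairs are
eligible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph_io import Pair, TemporalGraph, canonical_pair


@dataclass
class LinkSplit:
    """A single experiment's link partition plus sampled negatives."""

    induction_links: set[Pair]
    train_pos: set[Pair]
    test_pos: set[Pair]
    train_neg: set[Pair] = field(default_factory=set)
    test_neg: set[Pair] = field(default_factory=set)
    seed: int = 0

    def validate(self, g: TemporalGraph) -> None:
        """Assert every structural invariant against the source graph."""
        if not self.train_pos <= self.induction_links:
            raise ValueError("train positives must be a subset of induction links")
        if self.test_pos & self.induction_links:
            raise ValueError("test positives overlap induction links")
        negs = self.train_neg | self.test_neg
        if self.train_neg & self.test_neg:
            raise ValueError("train and test negatives overlap")
        if negs & g.links:
            raise ValueError("a sampled negative is a true link of the full graph")
        for u, v in negs:
            if u == v:
                raise ValueError("self-pair sampled as negative")
            if g.partition is not None and g.partition[u] == g.partition[v]:
                raise ValueError("intra-partition negative under bipartite graph")
        if self.train_neg and len(self.train_neg) != len(self.train_pos):
            raise ValueError("train negatives not 1:1 with train positives")
        if self.test_neg and len(self.test_neg) != len(self.test_pos):
            raise ValueError("test negatives not 1:1 with test positives")

    def induction_graph(self, g: TemporalGraph, keep_all_nodes: bool = True) -> TemporalGraph:
        """The graph predictors may look at: induction links only.

        All nodes of the full graph are kept by default, so entities that
        first appear in the test era are present as isolated nodes.
        """
        return g.subgraph_of_links(self.induction_links, keep_all_nodes=keep_all_nodes)


def random_slice(
    g: TemporalGraph,
    frac_induction: float = 0.60,
    frac_train: float = 0.10,
    seed: int = 0,
    sample_negs: bool = True,
) -> LinkSplit:
    """Connectivity-preserving random split (default 60/10/40).

    ``frac_induction`` of the links stay in the induction set and the rest
    become test positives; ``frac_train`` of all links (drawn uniformly
    from induction) are the predictor's training positives. A link may move
    to the test set only if its removal leaves its component connected, so
    the residual induction graph has exactly the input's component count.

    Once an edge is found to be a bridge of the residual graph it stays a
    bridge under any further deletions, so rejected edges are permanently
    ineligible; if the eligible pool is exhausted before the requested test
    fraction is reached the split is infeasible and an error reports the
    maximum removable fraction.
    """
    if not (0.0 < frac_train < frac_induction < 1.0):
        raise ValueError("need 0 < frac_train < frac_induction < 1")
    rng = np.random.default_rng(seed)
    links = sorted(g.links)
    n_links = len(links)
    n_test = round(n_links * (1.0 - frac_induction))
    n_train = round(n_links * frac_train)

    gx = g.to_networkx()
    order = rng.permutation(n_links)
    removed: set[Pair] = set()
    for idx in order:
        if len(removed) >= n_test:
            break
        u, v = links[idx]
        gx.remove_edge(u, v)
        if _connected_locally(gx, u, v):
            removed.add((u, v))
        else:
            gx.add_edge(u, v)  # bridge: permanently ineligible
    if len(removed) < n_test:
        raise ValueError(
            f"cannot remove {n_test}/{n_links} links while preserving "
            f"connectivity; at most {len(removed)} "
            f"({len(removed) / n_links:.1%}) are removable"
        )

    induction = set(links) - removed
    ind_sorted = sorted(induction)
    train_idx = rng.choice(len(ind_sorted), size=n_train, replace=False)
    train_pos = {ind_sorted[i] for i in train_idx}
    split = LinkSplit(
        induction_links=induction,
        train_pos=train_pos,
        test_pos=removed,
        seed=seed,
    )
    if sample_negs:
        split.train_neg, split.test_neg = sample_negatives(
            g, len(split.train_pos), len(split.test_pos), seed=seed
        )
    split.validate(g)
    return split


def _connected_locally(gx, u, v) -> bool:
    """BFS from u: is v still reachable after the edge (u,v) was removed?"""
    seen = {u}
    frontier = [u]
    while frontier:
        nxt = []
        for w in frontier:
            for x in gx.adj[w]:
                if x == v:
                    return True
                if x not in seen:
                    seen.add(x)
                    nxt.append(x)
        frontier = nxt
    return False


def time_slice(
    g: TemporalGraph,
    induction_end: int,
    train_start: int,
    test_end: int,
    seed: int = 0,
    sample_negs: bool = True,
) -> LinkSplit:
    """Chronological split: induction up to a cut year, test after it.

    The training window ``[train_start, induction_end]`` sits inside the
    induction era, so training positives are by construction a subset of
    the induction links. Links dated after ``test_end`` are ignored.
    """
    if g.year is None:
        raise ValueError("time_slice requires a graph with link years")
    if not (train_start <= induction_end < test_end):
        raise ValueError("need train_start <= induction_end < test_end")
    induction = {l for l in g.links if g.year[l] <= induction_end}
    train_pos = {l for l in induction if g.year[l] >= train_start}
    test_pos = {l for l in g.links if induction_end < g.year[l] <= test_end}
    for name, s in (("induction", induction), ("train", train_pos), ("test", test_pos)):
        if not s:
            raise ValueError(f"empty {name} slice for the given year windows")
    split = LinkSplit(
        induction_links=induction, train_pos=train_pos, test_pos=test_pos, seed=seed
    )
    if sample_negs:
        split.train_neg, split.test_neg = sample_negatives(
            g, len(train_pos), len(test_pos), seed=seed
        )
    split.validate(g)
    return split


def sample_negatives(
    g: TemporalGraph, n_train: int, n_test: int, seed: int = 0
) -> tuple[set[Pair], set[Pair]]:
    """Uniformly sample unlinked node pairs as negatives.

    Excludes every positive link of the full graph (all slices), forbids
    duplicates and self-pairs, keeps train and test negatives disjoint, and
    under a bipartition only draws cross-partition pairs. Reproducible per
    seed.
    """
    rng = np.random.default_rng(seed)
    n_needed = n_train + n_test
    if g.partition is not None:
        side_a = sorted(n for n in g.nodes if g.partition[n] == "A")
        side_b = sorted(n for n in g.nodes if g.partition[n] == "B")
        n_possible = len(side_a) * len(side_b) - len(g.links)
    else:
        nodes = sorted(g.nodes)
        n = len(nodes)
        n_possible = n * (n - 1) // 2 - len(g.links)
    if n_possible < n_needed:
        raise ValueError(
            f"requested {n_needed} negatives but only {n_possible} unlinked pairs exist"
        )

    chosen: list[Pair] = []
    seen: set[Pair] = set()
    # rejection sampling while the space is sparse enough; otherwise enumerate
    if n_needed <= 0.5 * n_possible:
        while len(chosen) < n_needed:
            if g.partition is not None:
                u = side_a[rng.integers(len(side_a))]
                v = side_b[rng.integers(len(side_b))]
            else:
                i, j = rng.integers(len(nodes)), rng.integers(len(nodes))
                if i == j:
                    continue
                u, v = nodes[i], nodes[j]
            pair = canonical_pair(u, v, g.partition)
            if pair in seen or pair in g.links:
                continue
            seen.add(pair)
            chosen.append(pair)
    else:
        if g.partition is not None:
            candidates = [
                canonical_pair(a, b, g.partition)
                for a in side_a
                for b in side_b
                if canonical_pair(a, b, g.partition) not in g.links
            ]
        else:
            candidates = [
                (nodes[i], nodes[j])
                for i in range(len(nodes))
                for j in range(i + 1, len(nodes))
                if (nodes[i], nodes[j]) not in g.links
            ]
        idx = rng.choice(len(candidates), size=n_needed, replace=False)
        chosen = [candidates[i] for i in idx]
    return set(chosen[:n_train]), set(chosen[n_train:])


# -- split manifest --------------------------------------------------------


def write_split(split: LinkSplit, g: TemporalGraph, outdir, meta: dict | None = None) -> None:
    """Write the five edge-list files plus a JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, pairs in (
        ("induction", split.induction_links),
        ("train_pos", split.train_pos),
        ("train_neg", split.train_neg),
        ("test_pos", split.test_pos),
        ("test_neg", split.test_neg),
    ):
        with open(outdir / f"{name}.edgelist", "w") as fh:
            for u, v in sorted(pairs):
                fh.write(f"{u}\t{v}\n")
    sidecar = {"seed": split.seed, "n_nodes": len(g.nodes), "n_links": len(g.links)}
    if meta:
        sidecar.update(meta)
    with open(outdir / "split.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_split(outdir) -> LinkSplit:
    outdir = Path(outdir)

    def _pairs(name: str) -> set[Pair]:
        out: set[Pair] = set()
        with open(outdir / f"{name}.edgelist") as fh:
            for line in fh:
                u, v = line.split()
                out.add((u, v))
        return out

    with open(outdir / "split.json") as fh:
        meta = json.load(fh)
    return LinkSplit(
        induction_links=_pairs("induction"),
        train_pos=_pairs("train_pos"),
        test_pos=_pairs("test_pos"),
        train_neg=_pairs("train_neg"),
        test_neg=_pairs("test_neg"),
        seed=int(meta.get("seed", 0)),
    )
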