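"""Synthetic community-structured graphs with edge timestamps.

The generator produces stochastic block model (SBM) graphs that mimic the
statistical structure real interaction and co-occurrence networks present
to a link predictor: dense communities (p_intra) against a sparse
background (p_inter), an optional two-partition drug/target-style
topology, and per-link years skewed toward late publication. Community
structure is what both neighbourhood heuristics and random-walk embeddings
exploit, so a strong-contrast SBM carries learnable signal for every
method under study, while the skewed timestamps reproduce the time-slice
pathology where a controllable fraction of nodes first appears after the
evaluation cut and reaches the predictor with no structural signal.

Bipartite mode pairs consecutive blocks (2i with 2i+1) into A/B
communities: pairs between paired blocks link with p_intra, other
cross-partition pairs with p_inter, and same-partition pairs never link.

Year sampling: with years ranked 1..m from earliest to latest, a link's
year is drawn with probability proportional to rank^skew — skew 0 is
uniform and larger skew concentrates link formation in late years.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Any

import numpy as np

from .graph_io import TemporalGraph, canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class SynthConfig:
    n_nodes: int = 200
    n_blocks: int = 4
    p_intra: float = 0.25
    p_inter: float = 0.02
    bipartite: bool = False
    year_range: tuple[int, int] = (1990, 2017)
    skew: float = 2.0
    unseen_frac_target: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2 or self.n_blocks < 1:
            raise ValueError("need at least 2 nodes and 1 block")
        if not (0.0 <= self.p_inter <= self.p_intra <= 1.0):
            raise ValueError("need 0 <= p_inter <= p_intra <= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("invalid year_range")
        if self.skew < 0:
            raise ValueError("skew must be non-negative")
        if self.bipartite and self.n_blocks % 2 != 0:
            raise ValueError("bipartite mode pairs blocks: n_blocks must be even")


def _blocks(cfg: SynthConfig) -> np.ndarray:
    """Contiguous, near-even block assignment for nodes 0..n-1."""
    return (np.arange(cfg.n_nodes) * cfg.n_blocks) // cfg.n_nodes


def _year_distribution(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    start, end = cfg.year_range
    years = np.arange(start, end + 1)
    ranks = np.arange(1, len(years) + 1, dtype=np.float64)
    probs = ranks ** cfg.skew
    probs /= probs.sum()
    return years, probs


def generate(cfg: SynthConfig) -> TemporalGraph:
    """Sample an SBM graph with skew-dated links."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    width = len(str(n - 1))
    names = [f"n{i:0{width}d}" for i in range(n)]
    block = _blocks(cfg)
    partition = None
    if cfg.bipartite:
        partition = {names[i]: ("A" if block[i] % 2 == 0 else "B") for i in range(n)}

    ii, jj = np.triu_indices(n, k=1)
    same_block = block[ii] == block[jj]
    if cfg.bipartite:
        side = block % 2
        cross = side[ii] != side[jj]
        paired = (block[ii] // 2) == (block[jj] // 2)
        prob = np.where(cross & paired, cfg.p_intra,
                        np.where(cross, cfg.p_inter, 0.0))
    else:
        prob = np.where(same_block, cfg.p_intra, cfg.p_inter)
    keep = rng.random(len(ii)) < prob
    links = {
        canonical_pair(names[a], names[b], partition)
        for a, b in zip(ii[keep], jj[keep])
    }

    years, probs = _year_distribution(cfg)
    drawn = rng.choice(years, size=len(links), p=probs)
    year = {link: int(y) for link, y in zip(sorted(links), drawn)}

    g = TemporalGraph.from_links(
        links, nodes=names, year=year, partition=partition
    )
    g.validate()
    return g


def first_link_years(g: TemporalGraph) -> dict[str, int | None]:
    """Per node, the year of its earliest link (None for isolated nodes)."""
    first: dict[str, int | None] = {n: None for n in g.nodes}
    assert g.year is not None
    for (u, v), y in g.year.items():
        for node in (u, v):
            if first[node] is None or y < first[node]:
                first[node] = y
    return first


def generate_split_scenario(
    cfg: SynthConfig, cut_year: int
) -> tuple[TemporalGraph, dict[str, Any]]:
    """Graph plus ground truth for time-slice experiments.

    Ground truth records each node's first-link year, each node's block,
    and the set of "unseen" nodes whose first link falls after
    ``cut_year`` (these reach a time-sliced predictor with no induction
    signal). If ``cfg.unseen_frac_target`` is set, extra nodes are pushed
    late by redrawing their incident links' years from the skew
    distribution truncated above the cut, until the target is met; an
    unreachable target logs a warning with the achieved fraction.
    """
    start, end = cfg.year_range
    if not (start <= cut_year <= end):
        raise ValueError(f"cut_year {cut_year} outside year_range {cfg.year_range}")
    g = generate(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    assert g.year is not None

    if cfg.unseen_frac_target is not None:
        years, probs = _year_distribution(cfg)
        late_mask = years > cut_year
        if not late_mask.any():
            logger.warning("no years after cut %d; unseen target unreachable", cut_year)
        else:
            late_years = years[late_mask]
            late_probs = probs[late_mask] / probs[late_mask].sum()
            target_n = math.ceil(cfg.unseen_frac_target * len(g.nodes))
            candidates = sorted(g.nodes)
            rng.shuffle(candidates)
            for node in candidates:
                unseen = _unseen_nodes(g, cut_year)
                if len(unseen) >= target_n:
                    break
                if node in unseen:
                    continue
                incident = [l for l in g.links if node in l]
                for link in incident:
                    g.year[link] = int(rng.choice(late_years, p=late_probs))
            achieved = len(_unseen_nodes(g, cut_year)) / len(g.nodes)
            if achieved + 1e-9 < cfg.unseen_frac_target:
                logger.warning(
                    "unseen_frac_target %.3f infeasible; achieved %.3f",
                    cfg.unseen_frac_target, achieved,
                )

    block = _blocks(cfg)
    width = len(str(cfg.n_nodes - 1))
    node_block = {f"n{i:0{width}d}": int(block[i]) for i in range(cfg.n_nodes)}
    truth = {
        "first_link_year": first_link_years(g),
        "block": node_block,
        "unseen_nodes": _unseen_nodes(g, cut_year),
        "cut_year": cut_year,
    }
    return g, truth


def _unseen_nodes(g: TemporalGraph, cut_year: int) -> set[str]:
    """Nodes with no link dated at or before the cut (isolated ones count)."""
    return {
        n for n, y in first_link_years(g).items() if y is None or y > cut_year
    }
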