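"""Random-walk node embeddings.

Walk generation covers both the uniform first-order walks of DeepWalk and
the p/q-biased second-order walks of node2vec (return weight 1/p, weight 1
for moving to a neighbour of the previous node, 1/q otherwise). Walk
corpora are treated as sentences and fed to a skip-gram trainer; the
trainer is pluggable — any callable mapping (corpus, config) to vectors
satisfies the contract — and the default backend is a compact,
deterministic skip-gram with negative sampling implemented on numpy.

Post-processing utilities cover the concatenate-and-L2-normalize scheme
used to merge first- and second-order proximity embeddings, and the
random-initialization fallback for nodes that never occur in the
induction slice (those nodes carry no structural signal and keep their
initial vectors, flagged ``random-init``).

Defaults follow the standard desk settings for these methods: window 10,
walk length 40, 10 walks per vertex, 100 dimensions, p=2, q=4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .graph_io import TemporalGraph

Walk = list[str]


@dataclass
class WalkConfig:
    walk_length: int = 40
    walks_per_vertex: int = 10
    window: int = 10
    dimensions: int = 100
    p: float = 2.0  # return parameter (biased mode only)
    q: float = 4.0  # in-out parameter (biased mode only)
    epochs: int = 3  # trainer passes over the pair list
    negative: int = 5  # negative samples per positive pair
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("walk_length", "walks_per_vertex", "window", "dimensions",
                     "epochs", "negative"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


@dataclass
class EmbeddingTable:
    """node-id → vector, with provenance (trained vs random-init fallback)."""

    vectors: dict[str, np.ndarray]
    trained_flag: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent vector shapes: {dims}")
        for node in self.vectors:
            self.trained_flag.setdefault(node, "trained")

    @property
    def dimension(self) -> int:
        if not self.vectors:
            raise ValueError("empty table has no dimension")
        return next(iter(self.vectors.values())).shape[0]

    def __contains__(self, node: str) -> bool:
        return node in self.vectors

    def __getitem__(self, node: str) -> np.ndarray:
        return self.vectors[node]

    def __len__(self) -> int:
        return len(self.vectors)

    def random_init_fraction(self) -> float:
        if not self.vectors:
            return 0.0
        n = sum(1 for f in self.trained_flag.values() if f == "random-init")
        return n / len(self.vectors)

    # word2vec text format: header "<count> <dim>", then "<id> <v1> ... <vd>"
    def write_word2vec(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for node in sorted(self.vectors):
                vals = " ".join(f"{x:.8g}" for x in self.vectors[node])
                fh.write(f"{node} {vals}\n")

    @classmethod
    def read_word2vec(cls, path) -> "EmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        with open(path) as fh:
            header = fh.readline().split()
            count, dim = int(header[0]), int(header[1])
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]], dtype=np.float64)
        if len(vectors) != count:
            raise ValueError(f"header promised {count} vectors, file holds {len(vectors)}")
        for v in vectors.values():
            if v.shape[0] != dim:
                raise ValueError("vector length disagrees with header dimension")
        return cls(vectors=vectors)


# -- walk generation -------------------------------------------------------


def generate_walks(g: TemporalGraph, cfg: WalkConfig, mode: str = "uniform") -> list[Walk]:
    """walks_per_vertex truncated random walks from every node.

    ``uniform``: next node uniform over current neighbours. ``biased``:
    second-order walk with unnormalized weight 1/p for returning to the
    previous node, 1 for a candidate adjacent to the previous node, 1/q
    otherwise. Isolated nodes yield length-1 walks. Seeded and
    reproducible; walk order is a seeded shuffle of (start, repeat) pairs.
    """
    if mode not in ("uniform", "biased"):
        raise ValueError(f"mode must be 'uniform' or 'biased', got {mode!r}")
    if not g.nodes:
        raise ValueError("cannot walk an empty graph")
    rng = np.random.default_rng(cfg.seed)
    adj = {n: sorted(g.adjacency[n]) for n in g.nodes}
    starts = [n for n in sorted(g.nodes) for _ in range(cfg.walks_per_vertex)]
    rng.shuffle(starts)
    walks: list[Walk] = []
    for start in starts:
        walk = [start]
        while len(walk) < cfg.walk_length:
            cur = walk[-1]
            nbrs = adj[cur]
            if not nbrs:
                break
            if mode == "uniform" or len(walk) == 1:
                nxt = nbrs[rng.integers(len(nbrs))]
            else:
                prev = walk[-2]
                prev_nbrs = g.adjacency[prev]
                w = np.empty(len(nbrs))
                for i, cand in enumerate(nbrs):
                    if cand == prev:
                        w[i] = 1.0 / cfg.p
                    elif cand in prev_nbrs:
                        w[i] = 1.0
                    else:
                        w[i] = 1.0 / cfg.q
                w /= w.sum()
                nxt = nbrs[rng.choice(len(nbrs), p=w)]
            walk.append(nxt)
        walks.append(walk)
    return walks


def write_walks(walks: Sequence[Walk], path) -> None:
    with open(path, "w") as fh:
        for w in walks:
            fh.write(" ".join(w) + "\n")


def read_walks(path) -> list[Walk]:
    with open(path) as fh:
        return [line.split() for line in fh if line.strip()]


# -- skip-gram trainer (default pluggable backend) -------------------------


def _corpus_pairs(walks: Sequence[Walk], window: int, index: dict[str, int],
                  rng: np.random.Generator) -> np.ndarray:
    """(center, context) index pairs with word2vec-style dynamic windows."""
    centers: list[int] = []
    contexts: list[int] = []
    for walk in walks:
        ids = [index[n] for n in walk]
        # per-position reduced window, as in the reference word2vec trainer:
        # effective window drawn uniformly from 1..window
        reduced = rng.integers(1, window + 1, size=len(ids))
        for i, c in enumerate(ids):
            lo = max(0, i - int(reduced[i]))
            hi = min(len(ids), i + int(reduced[i]) + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    return np.array([centers, contexts], dtype=np.int64)


def sgns_train(walks: Sequence[Walk], cfg: WalkConfig) -> dict[str, np.ndarray]:
    """Skip-gram with negative sampling over a walk corpus.

    Minibatch SGD on the standard SGNS objective: for each (center,
    context) pair within the window, push the pair's vectors together and
    push ``cfg.negative`` unigram^0.75-sampled negatives apart. Fully
    deterministic for a fixed seed (single-threaded numpy).
    """
    if not walks:
        raise ValueError("empty walk corpus")
    rng = np.random.default_rng(cfg.seed)
    vocab = sorted({n for w in walks for n in w})
    index = {n: i for i, n in enumerate(vocab)}
    V, D = len(vocab), cfg.dimensions

    counts = np.zeros(V)
    for w in walks:
        for n in w:
            counts[index[n]] += 1
    noise = counts ** 0.75
    noise /= noise.sum()

    W_in = rng.uniform(-0.5 / D, 0.5 / D, size=(V, D))
    W_out = np.zeros((V, D))

    pairs = _corpus_pairs(walks, cfg.window, index, rng)
    n_pairs = pairs.shape[1]
    batch = 1024
    k = cfg.negative
    for epoch in range(cfg.epochs):
        # linear learning-rate decay over all epochs, floored at 1e-4
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            frac = (epoch * n_pairs + start) / (cfg.epochs * n_pairs)
            lr = max(cfg.learning_rate * (1.0 - frac), 1e-4)
            idx = order[start : start + batch]
            c = pairs[0, idx]
            o = pairs[1, idx]
            neg = rng.choice(V, size=(len(idx), k), p=noise)

            vc = W_in[c]                      # (B, D)
            vo = W_out[o]                     # (B, D)
            vn = W_out[neg]                   # (B, k, D)

            pos_score = 1.0 / (1.0 + np.exp(-np.einsum("bd,bd->b", vc, vo)))
            neg_score = 1.0 / (1.0 + np.exp(-np.einsum("bd,bkd->bk", vc, vn)))

            g_pos = (pos_score - 1.0)[:, None]          # (B, 1)
            g_neg = neg_score[:, :, None]               # (B, k, 1)

            grad_c = g_pos * vo + np.einsum("bko,bkd->bd", g_neg, vn)
            np.add.at(W_out, o, -lr * g_pos * vc)
            np.add.at(W_out, neg.ravel(),
                      (-lr * g_neg * vc[:, None, :]).reshape(-1, D))
            np.add.at(W_in, c, -lr * grad_c)

    return {n: W_in[index[n]].copy() for n in vocab}


def train_embeddings(
    walks: Sequence[Walk],
    cfg: WalkConfig,
    trainer: Callable[[Sequence[Walk], WalkConfig], dict[str, np.ndarray]] = sgns_train,
) -> EmbeddingTable:
    """Train node vectors from a walk corpus via a pluggable trainer.

    Contract: every node occurring in the corpus receives a vector of
    ``cfg.dimensions`` reals, and nodes co-occurring within the window end
    up closer in cosine similarity than random node pairs (a statistical
    tendency, asserted over populations, not per pair).
    """
    if not walks:
        raise ValueError("empty walk corpus")
    vectors = trainer(walks, cfg)
    for node, vec in vectors.items():
        if vec.shape != (cfg.dimensions,):
            raise ValueError(f"trainer returned shape {vec.shape} for {node!r}")
    return EmbeddingTable(vectors=vectors,
                          trained_flag={n: "trained" for n in vectors})


def embed_graph(g: TemporalGraph, cfg: WalkConfig, mode: str = "uniform",
                trainer=sgns_train) -> EmbeddingTable:
    """Walks + training + fallback completion for every node of ``g``."""
    walks = generate_walks(g, cfg, mode=mode)
    table = train_embeddings(walks, cfg, trainer=trainer)
    return complete_table(table, g.nodes, cfg.dimensions, seed=cfg.seed)


# -- post-processing -------------------------------------------------------


def line_postprocess(first: EmbeddingTable, second: EmbeddingTable) -> EmbeddingTable:
    """Concatenate first- and second-order proximity vectors, L2-normalize.

    Each input table carries half the target dimension; the concatenated
    vector is divided by its Euclidean norm (all-zero vectors pass through
    unnormalized).
    """
    if set(first.vectors) != set(second.vectors):
        raise ValueError("tables cover different node sets")
    out: dict[str, np.ndarray] = {}
    flags: dict[str, str] = {}
    for node in first.vectors:
        cat = np.concatenate([first.vectors[node], second.vectors[node]])
        norm = np.linalg.norm(cat)
        out[node] = cat / norm if norm > 0 else cat
        f1 = first.trained_flag.get(node, "trained")
        f2 = second.trained_flag.get(node, "trained")
        flags[node] = "trained" if (f1 == f2 == "trained") else "random-init"
    return EmbeddingTable(vectors=out, trained_flag=flags)


def complete_table(t: EmbeddingTable, all_nodes: set[str], dim: int,
                   seed: int = 0) -> EmbeddingTable:
    """Give every node a vector; missing nodes get flagged random vectors.

    Nodes absent from the trained table (never seen in the induction
    slice) receive seeded i.i.d. uniform [-0.5/dim, 0.5/dim] components —
    the usual embedding-matrix initialization — flagged ``random-init``.
    """
    if t.vectors and t.dimension != dim:
        raise ValueError(f"table dimension {t.dimension} != requested {dim}")
    rng = np.random.default_rng(seed)
    vectors = {n: v.copy() for n, v in t.vectors.items()}
    flags = dict(t.trained_flag)
    for node in sorted(all_nodes - vectors.keys()):
        vectors[node] = rng.uniform(-0.5 / dim, 0.5 / dim, size=dim)
        flags[node] = "random-init"
    return EmbeddingTable(vectors=vectors, trained_flag=flags)
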