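"""Node-pair combination operators and the minimalist neural link predictor.

A link candidate (u, v) is turned into a single feature vector by one of
five element-wise operators on the node embeddings f(u), f(v):

    average      (f_i(u) + f_i(v)) / 2
    concatenate  f(u) ‖ f(v)            (doubles the dimension)
    hadamard     f_i(u) · f_i(v)
    weighted_l1  |f_i(u) − f_i(v)|
    weighted_l2  |f_i(u) − f_i(v)|²

The predictor itself is deliberately minimal — a single hidden layer of
100 rectified linear units feeding one sigmoid output, trained on
cross-entropy for exactly 7 epochs — so that ranking quality reflects the
node representations rather than model capacity. Remaining optimization
knobs (adam at its conventional rate, minibatch 128) are fixed defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

from .embedding import EmbeddingTable
from .graph_io import Pair
from .ranking import ScoredRanking

COMBINE_OPS = ("average", "concatenate", "hadamard", "weighted_l1", "weighted_l2")


def combine(x: np.ndarray, y: np.ndarray, op: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if op == "average":
        return (x + y) / 2.0
    if op == "concatenate":
        return np.concatenate([x, y])
    if op == "hadamard":
        return x * y
    if op == "weighted_l1":
        return np.abs(x - y)
    if op == "weighted_l2":
        return (x - y) ** 2
    raise ValueError(f"unknown combine op {op!r}; choose from {COMBINE_OPS}")


def combine_pairs(pairs: Sequence[Pair], emb: EmbeddingTable, op: str) -> np.ndarray:
    """Stack combined vectors for a pair list (canonical order preserved).

    Endpoints are fed in the pair's canonical order (lexicographic;
    A-side first on bipartite graphs), which makes the asymmetric
    concatenate operator order-independent in practice.
    """
    rows = []
    for u, v in pairs:
        if u not in emb or v not in emb:
            missing = u if u not in emb else v
            raise KeyError(
                f"node {missing!r} has no embedding; run complete_table first"
            )
        rows.append(combine(emb[u], emb[v], op))
    return np.vstack(rows) if rows else np.empty((0, 0))


@dataclass
class PredictorConfig:
    hidden_units: int = 100
    epochs: int = 7
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("hidden_units, epochs and batch_size must be positive")


def train_predictor(
    train_pos_vecs: np.ndarray,
    train_neg_vecs: np.ndarray,
    cfg: PredictorConfig | None = None,
) -> MLPClassifier:
    """Fit the feed-forward link predictor on combined link vectors.

    Exactly ``cfg.epochs`` passes of adam on log-loss; no early stopping,
    no dropout, no validation split. Seeded initialization makes the loss
    trajectory reproducible.
    """
    cfg = cfg or PredictorConfig()
    pos = np.asarray(train_pos_vecs, dtype=np.float64)
    neg = np.asarray(train_neg_vecs, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    if pos.shape[1] != neg.shape[1]:
        raise ValueError("positive and negative vectors disagree in dimension")
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    model = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        activation="relu",
        solver="adam",
        batch_size=min(cfg.batch_size, len(X)),
        max_iter=cfg.epochs,
        shuffle=True,
        random_state=cfg.seed,
        early_stopping=False,
        n_iter_no_change=cfg.epochs + 1,  # never stop on plateau
    )
    import warnings

    with warnings.catch_warnings():
        # 7 epochs is the training budget, not a convergence failure
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        model.fit(X, y)
    return model


def predict(
    model: MLPClassifier,
    pairs: Sequence[Pair],
    emb: EmbeddingTable,
    op: str,
    labels: Sequence[int] | None = None,
    method: str = "",
) -> ScoredRanking:
    """Probability of link formation per pair, as a sorted ranking."""
    if labels is None:
        labels = [0] * len(pairs)
    if not pairs:
        return ScoredRanking(entries=[], method=method)
    X = combine_pairs(pairs, emb, op)
    proba = model.predict_proba(X)[:, 1]
    return ScoredRanking.from_scores(pairs, proba, labels, method=method)
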