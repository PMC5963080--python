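"""Ranked lists of scored candidate links.

Every scoring route (neighbourhood heuristics and neural predictors alike)
produces a :class:`ScoredRanking`: candidate pairs sorted by descending
score with a deterministic lexicographic tie-break, each carrying its
ground-truth label. Metrics consume only this structure, so methods are
compared on identical footing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

Pair = tuple[str, str]


@dataclass(frozen=True)
class RankedEntry:
    pair: Pair
    score: float
    label: int  # 1 = true link, 0 = sampled negative


@dataclass
class ScoredRanking:
    """Candidate links sorted by descending score, ties broken by pair id."""

    entries: list[RankedEntry]
    method: str = ""

    @classmethod
    def from_scores(
        cls,
        pairs: Sequence[Pair],
        scores: Sequence[float],
        labels: Sequence[int],
        method: str = "",
    ) -> "ScoredRanking":
        if not (len(pairs) == len(scores) == len(labels)):
            raise ValueError("pairs, scores and labels must have equal length")
        entries = [
            RankedEntry(tuple(p), float(s), int(l))
            for p, s, l in zip(pairs, scores, labels)
        ]
        entries.sort(key=lambda e: (-e.score, e.pair))
        return cls(entries=entries, method=method)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def scores(self) -> list[float]:
        return [e.score for e in self.entries]

    @property
    def labels(self) -> list[int]:
        return [e.label for e in self.entries]

    @property
    def pairs(self) -> list[Pair]:
        return [e.pair for e in self.entries]

    def n_positives(self) -> int:
        return sum(e.label for e in self.entries)

    def rank_of(self, pair: Pair) -> int:
        """1-based rank of a pair after tie-breaking."""
        for i, e in enumerate(self.entries, start=1):
            if e.pair == pair:
                return i
        raise KeyError(f"pair {pair!r} not in ranking")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(f"{e.pair[0]}\t{e.pair[1]}\t{e.score:.10g}\t{e.label}\n")

    @classmethod
    def read_tsv(cls, path, method: str = "") -> "ScoredRanking":
        pairs: list[Pair] = []
        scores: list[float] = []
        labels: list[int] = []
        with open(path) as fh:
            for line in fh:
                u, v, s, l = line.split("\t")
                pairs.append((u, v))
                scores.append(float(s))
                labels.append(int(l))
        return cls.from_scores(pairs, scores, labels, method=method)


def merge_labelled_pairs(
    positives: Iterable[Pair], negatives: Iterable[Pair]
) -> tuple[list[Pair], list[int]]:
    """Interleave positive and negative pairs into a single labelled list."""
    pairs: list[Pair] = []
    labels: list[int] = []
    for p in sorted(positives):
        pairs.append(p)
        labels.append(1)
    for p in sorted(negatives):
        pairs.append(p)
        labels.append(0)
    return pairs, labels
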