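"""Ranking metrics for link prediction, and cross-run aggregation.

Five metrics in two families. **Link-equality** metrics pool all candidate
links, so hub nodes with many easy links dominate: AUROC, area under the
precision-recall curve, and precision@k (k derived as a fraction of the
positive count, since graph sizes vary). **Node-equality** metrics average
per-node performance with equal weight, exposing how a predictor does
across the breadth of the graph: mean average precision (MAP) and averaged
R-precision, both computed over each node's sublist of the single global
ranking.

Ties are resolved lexicographically before any rank-based computation, so
every metric is deterministic; AUROC alone uses the standard half-credit
convention on the raw scores (the probability a random positive outranks a
random negative).

Aggregation follows the mean-of-runs protocol: per metric, methods are
compared to the best-scoring one with a two-tailed two-sample t-test at
α = 0.05. With typical run counts of three the test has little power;
"not-different" verdicts should be read accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .ranking import ScoredRanking

METRIC_NAMES = ("auroc", "aupr", "precision_at_k", "map", "r_precision")

ALPHA = 0.05


def auroc(r: ScoredRanking) -> float:
    """Probability a random positive outranks a random negative (ties half)."""
    labels = r.labels
    if sum(labels) == 0 or sum(labels) == len(labels):
        raise ValueError("AUROC needs at least one positive and one negative")
    return float(roc_auc_score(labels, r.scores))


def aupr(r: ScoredRanking) -> float:
    """Area under the precision-recall step curve.

    Summation of precision at each positive's (tie-broken) rank, divided
    by the number of positives — each positive contributes one equal
    recall increment.
    """
    labels = r.labels
    n_pos = sum(labels)
    if n_pos == 0:
        raise ValueError("AUPR needs at least one positive")
    hits = 0
    total = 0.0
    for i, lab in enumerate(labels, start=1):
        if lab:
            hits += 1
            total += hits / i
    return total / n_pos


def precision_at_k(r: ScoredRanking, k_ratio: float = 0.3) -> float:
    """Fraction of true positives among the top k = ceil(k_ratio · P) entries."""
    if not 0.0 < k_ratio <= 1.0:
        raise ValueError("k_ratio must be in (0, 1]")
    if len(r) == 0:
        raise ValueError("empty ranking")
    n_pos = r.n_positives()
    if n_pos == 0:
        raise ValueError("precision@k needs at least one positive")
    k = math.ceil(k_ratio * n_pos)
    top = r.labels[:k]
    return sum(top) / len(top)


def per_node_lists(r: ScoredRanking) -> dict[str, list]:
    """Each node's sublist of the global ranking (global order preserved)."""
    out: dict[str, list] = {}
    for e in r.entries:
        for node in e.pair:
            out.setdefault(node, []).append(e)
    return out


def _average_precision(entries) -> float | None:
    hits = 0
    total = 0.0
    for i, e in enumerate(entries, start=1):
        if e.label:
            hits += 1
            total += hits / i
    return total / hits if hits else None


def mean_average_precision(r: ScoredRanking) -> float:
    """Unweighted mean over nodes of the node's average precision.

    A node's AP is precision at each of its positives' ranks within its
    own sublist, averaged; nodes with no test positive have undefined AP
    and are excluded (the standard IR convention).
    """
    aps = [ap for ap in (_average_precision(lst) for lst in per_node_lists(r).values())
           if ap is not None]
    if not aps:
        raise ValueError("MAP needs at least one node with a positive")
    return float(np.mean(aps))


def averaged_r_precision(r: ScoredRanking) -> float:
    """Unweighted mean over nodes of precision within the node's top R.

    R is the node's own true-positive count; only the top R entries of its
    sublist are inspected.
    """
    vals = []
    for entries in per_node_lists(r).values():
        n_pos = sum(e.label for e in entries)
        if n_pos == 0:
            continue
        vals.append(sum(e.label for e in entries[:n_pos]) / n_pos)
    if not vals:
        raise ValueError("R-precision needs at least one node with a positive")
    return float(np.mean(vals))


def compute_metrics(r: ScoredRanking, k_ratio: float = 0.3) -> dict[str, float]:
    """All five metrics for one ranking."""
    return {
        "auroc": auroc(r),
        "aupr": aupr(r),
        "precision_at_k": precision_at_k(r, k_ratio),
        "map": mean_average_precision(r),
        "r_precision": averaged_r_precision(r),
    }


# -- aggregation across runs -----------------------------------------------


@dataclass
class MetricReport:
    """Per-method, per-metric run values with means, sds and verdicts.

    ``significance[metric][method]`` is ``"different"`` or
    ``"not-different"`` versus the best-mean method for that metric (the
    best method compares to itself as not-different).
    """

    runs: dict[str, list[dict[str, float]]]
    k_ratio: float = 0.3
    mean: dict[str, dict[str, float]] = field(default_factory=dict)
    sd: dict[str, dict[str, float]] = field(default_factory=dict)
    best: dict[str, str] = field(default_factory=dict)
    significance: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(next(iter(self.runs.values())))

    def values(self, method: str, metric: str) -> list[float]:
        return [run[metric] for run in self.runs[method]]

    def to_rows(self) -> list[dict]:
        rows = []
        for method, run_list in sorted(self.runs.items()):
            for i, run in enumerate(run_list):
                for metric, value in run.items():
                    rows.append({"method": method, "metric": metric,
                                 "run": i, "value": value})
        return rows

    def summary_table(self) -> str:
        """Mean table in the conventional layout: bold best, * = not
        significantly different from best."""
        lines = ["method\t" + "\t".join(METRIC_NAMES)]
        for method in sorted(self.runs):
            cells = []
            for metric in METRIC_NAMES:
                v = self.mean[method][metric]
                cell = f"{100 * v:.2f}"
                if self.best[metric] == method:
                    cell = f"**{cell}**"
                elif self.significance[metric][method] == "not-different":
                    cell += "*"
                cells.append(cell)
            lines.append(method + "\t" + "\t".join(cells))
        return "\n".join(lines)


def two_tailed_verdict(a: list[float], b: list[float], alpha: float = ALPHA) -> str:
    """Welch-free two-sample t-test verdict with degenerate fast paths.

    Identical value multisets are trivially not-different; two groups each
    with zero variance but unequal means are trivially different (the t
    statistic diverges).
    """
    a_arr, b_arr = np.asarray(a, float), np.asarray(b, float)
    if np.array_equal(np.sort(a_arr), np.sort(b_arr)):
        return "not-different"
    if a_arr.std() == 0.0 and b_arr.std() == 0.0:
        return "different"  # unequal constant groups
    import warnings

    with warnings.catch_warnings():
        # near-identical groups trigger a scipy precision-loss warning; the
        # verdict for such groups is dominated by the tiny mean difference
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a_arr, b_arr)
    return "different" if p < alpha else "not-different"


def aggregate_runs(runs: dict[str, list[dict[str, float]]],
                   k_ratio: float = 0.3, alpha: float = ALPHA) -> MetricReport:
    """Aggregate per-run metric dicts into means, sds and verdicts.

    ``runs`` maps method name to its list of per-run metric dicts; all
    methods need at least two runs and equal run counts.
    """
    counts = {m: len(v) for m, v in runs.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"unequal run counts across methods: {counts}")
    if next(iter(counts.values())) < 2:
        raise ValueError("need at least two runs per method to aggregate")

    report = MetricReport(runs=runs, k_ratio=k_ratio)
    for method, run_list in runs.items():
        report.mean[method] = {m: float(np.mean([r[m] for r in run_list]))
                               for m in METRIC_NAMES}
        report.sd[method] = {m: float(np.std([r[m] for r in run_list], ddof=1))
                             for m in METRIC_NAMES}
    for metric in METRIC_NAMES:
        best = max(runs, key=lambda meth: report.mean[meth][metric])
        report.best[metric] = best
        best_vals = [r[metric] for r in runs[best]]
        verdicts = {}
        for method, run_list in runs.items():
            vals = [r[metric] for r in run_list]
            verdicts[method] = two_tailed_verdict(best_vals, vals, alpha)
        report.significance[metric] = verdicts
    return report


def write_report_tsv(report: MetricReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("method\tmetric\trun\tvalue\n")
        for row in report.to_rows():
            fh.write(f"{row['method']}\t{row['metric']}\t{row['run']}\t{row['value']:.6f}\n")
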