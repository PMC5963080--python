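"""Ranking metrics against brute-force oracles, plus run aggregation."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from linkbench.metrics import (
    aggregate_runs,
    auroc,
    aupr,
    averaged_r_precision,
    compute_metrics,
    mean_average_precision,
    per_node_lists,
    precision_at_k,
    two_tailed_verdict,
)
from linkbench.ranking import ScoredRanking

from oracles import oracle_ap, oracle_auroc, oracle_node_metrics, oracle_p_at_k


def ranking_from_labels(labels, pairs=None):
    """A ranking whose (tie-free) order realises the given label sequence."""
    n = len(labels)
    if pairs is None:
        pool = [
            (f"v{i}", f"v{j}") for i in range(6) for j in range(i + 1, 6)
        ]
        pairs = pool[:n]
    scores = list(range(n, 0, -1))
    return ScoredRanking.from_scores(pairs, scores, labels)


class TestHandComputedValues:
    def test_auroc_perfect(self):
        assert auroc(ranking_from_labels([1, 1, 0, 0])) == 1.0

    def test_auroc_alternating_three_quarters(self):
        # [+,-,+,-]: 4 positive-negative pairs, 3 concordant
        assert auroc(ranking_from_labels([1, 0, 1, 0])) == pytest.approx(0.75)

    def test_auroc_half_credit_for_ties(self):
        r = ScoredRanking.from_scores(
            [("a", "b"), ("a", "c"), ("b", "c"), ("b", "d")],
            [1.0, 1.0, 1.0, 0.0], [1, 0, 1, 0],
        )
        # two positives tie with one negative (0.5 each); both beat the 0.0
        assert auroc(r) == pytest.approx(oracle_auroc(r.labels, r.scores))
        assert auroc(r) == pytest.approx(0.75)

    def test_auroc_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc(ranking_from_labels([1, 1]))

    def test_aupr_perfect(self):
        assert aupr(ranking_from_labels([1, 1, 0])) == 1.0

    def test_aupr_step_curve_example(self):
        assert aupr(ranking_from_labels([1, 0, 1])) == pytest.approx(5 / 6)

    def test_aupr_positives_ranked_last(self):
        # positions 9 and 10 of 10: (1/9 + 2/10) / 2
        labels = [0] * 8 + [1, 1]
        assert aupr(ranking_from_labels(labels)) == pytest.approx(
            (1 / 9 + 2 / 10) / 2
        )

    def test_precision_at_k_all_hits(self):
        labels = [1] * 3 + [0] * 4 + [1] * 7  # 10 positives -> k = 3
        assert precision_at_k(ranking_from_labels(labels), 0.3) == 1.0

    def test_precision_at_k_inverted(self):
        labels = [0] * 5 + [1] * 5
        assert precision_at_k(ranking_from_labels(labels), 0.3) == 0.0

    def test_map_single_node_list(self):
        r = ScoredRanking.from_scores(
            [("a", "b"), ("a", "c"), ("a", "d")], [3, 2, 1], [1, 0, 1]
        )
        # node a sees [+,-,+] -> AP = (1 + 2/3)/2; b, c, d are singletons
        assert mean_average_precision(r) == pytest.approx(
            np.mean([(1 + 2 / 3) / 2, 1.0, 1.0]), abs=1e-12
        )

    def test_map_is_unweighted_over_nodes(self):
        # hub node with AP 1.0 and a node with AP 0.5 average to 0.75
        # regardless of how many entries the hub list has
        r = ScoredRanking.from_scores(
            [("h", "x1"), ("h", "x2"), ("h", "x3"), ("z", "w1"), ("z", "w2")],
            [5, 4, 3, 2, 1],
            [1, 1, 1, 0, 1],
        )
        got = mean_average_precision(r)
        exp_map, exp_rp = oracle_node_metrics(r.pairs, r.labels)
        assert got == pytest.approx(exp_map)

    def test_r_precision_examples(self):
        # node with 2 positives at local ranks 1 and 3 -> R=2 -> 0.5
        r = ScoredRanking.from_scores(
            [("a", "b"), ("a", "c"), ("a", "d")], [3, 2, 1], [1, 0, 1]
        )
        sub = [1, 0, 1]
        assert sum(sub[:2]) / 2 == 0.5
        _, exp_rp = oracle_node_metrics(r.pairs, r.labels)
        assert averaged_r_precision(r) == pytest.approx(exp_rp)


class TestPerNodeLists:
    def test_each_pair_touches_two_nodes(self):
        r = ranking_from_labels([1, 0, 1, 0, 1])
        lists = per_node_lists(r)
        assert sum(len(v) for v in lists.values()) == 2 * len(r)

    def test_global_order_preserved(self):
        r = ScoredRanking.from_scores(
            [("a", "b"), ("a", "c"), ("b", "c")], [3, 1, 2], [1, 0, 1]
        )
        lists = per_node_lists(r)
        assert [e.pair for e in lists["a"]] == [("a", "b"), ("a", "c")]
        assert [e.pair for e in lists["c"]] == [("b", "c"), ("a", "c")]

    def test_node_absent_from_pairs_absent_from_map(self):
        r = ranking_from_labels([1, 0])
        assert "zz" not in per_node_lists(r)


class TestExhaustiveOracleEquivalence:
    """All label patterns on rankings of length <= 8, several pair layouts."""

    @pytest.mark.parametrize("n", range(2, 9))
    def test_all_label_patterns(self, n):
        rng = np.random.default_rng(n)
        pool = [(f"v{i}", f"v{j}") for i in range(6) for j in range(i + 1, 6)]
        layouts = [pool[:n]]
        for _ in range(2):  # sampled pair permutations
            idx = rng.permutation(len(pool))[:n]
            layouts.append([pool[i] for i in sorted(idx)])
        for pairs in layouts:
            for labels in itertools.product([0, 1], repeat=n):
                if 0 < sum(labels) < n:
                    r = ranking_from_labels(list(labels), pairs=pairs)
                    assert auroc(r) == pytest.approx(
                        oracle_auroc(r.labels, r.scores))
                    assert aupr(r) == pytest.approx(oracle_ap(r.labels))
                    assert precision_at_k(r, 0.3) == pytest.approx(
                        oracle_p_at_k(r.labels, 0.3))
                    exp_map, exp_rp = oracle_node_metrics(r.pairs, r.labels)
                    assert mean_average_precision(r) == pytest.approx(exp_map)
                    assert averaged_r_precision(r) == pytest.approx(exp_rp)

    def test_aupr_cross_checked_against_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 40))
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.sum() in (0, n):
                continue
            r = ranking_from_labels(
                list(labels),
                pairs=[(f"a{i:02d}", f"b{i:02d}") for i in range(n)],
            )
            # distinct descending scores: step-sum equals sklearn AP exactly
            assert aupr(r) == pytest.approx(
                average_precision_score(r.labels, r.scores))


class TestInvariances:
    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(50) < 0.5).astype(int)
        labels[0], labels[1] = 1, 0
        scores = rng.normal(size=50)
        pairs = [(f"a{i:02d}", f"b{i:02d}") for i in range(50)]
        r1 = ScoredRanking.from_scores(pairs, scores, labels)
        r2 = ScoredRanking.from_scores(pairs, np.exp(3 * scores), labels)
        assert auroc(r1) == pytest.approx(auroc(r2))

    def test_node_metrics_unaffected_by_other_nodes_hubness(self):
        # duplicate a hub's entries: other nodes' AP contributions unchanged
        base = [(("a", "b"), 9, 1), (("a", "c"), 8, 0), (("x", "y"), 7, 1)]
        hub_extra = [(("h", f"k{i}"), 6 - i, 1) for i in range(3)]
        def build(entries):
            p, s, l = zip(*entries)
            return ScoredRanking.from_scores(p, s, l)
        lists1 = per_node_lists(build(base))
        lists2 = per_node_lists(build(base + hub_extra))
        for node in ("a", "x", "y"):
            assert [e.pair for e in lists1[node]] == [e.pair for e in lists2[node]]


class TestAggregation:
    def test_identical_runs_not_different(self):
        runs = {
            "m1": [dict.fromkeys(
                ("auroc", "aupr", "precision_at_k", "map", "r_precision"), 0.9
            )] * 3,
        }
        runs["m2"] = [dict(r) for r in runs["m1"]]
        rep = aggregate_runs(runs)
        assert rep.sd["m1"]["auroc"] == 0.0
        assert all(v == "not-different"
                   for v in rep.significance["auroc"].values())

    def test_zero_variance_unequal_groups_are_different(self):
        assert two_tailed_verdict([0.9] * 3, [0.5] * 3) == "different"

    def test_verdict_matches_textbook_t_computation(self):
        a, b = [0.80, 0.81, 0.79], [0.80, 0.80, 0.81]
        # pooled two-sample t by hand
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        sp = math.sqrt(((len(a) - 1) * va + (len(b) - 1) * vb)
                       / (len(a) + len(b) - 2))
        t = (ma - mb) / (sp * math.sqrt(1 / len(a) + 1 / len(b)))
        from scipy import stats
        p = 2 * stats.t.sf(abs(t), len(a) + len(b) - 2)
        expected = "different" if p < 0.05 else "not-different"
        assert two_tailed_verdict(a, b) == expected

    def test_unequal_run_counts_rejected(self):
        metrics = dict.fromkeys(
            ("auroc", "aupr", "precision_at_k", "map", "r_precision"), 0.5)
        with pytest.raises(ValueError, match="unequal"):
            aggregate_runs({"a": [metrics] * 3, "b": [metrics] * 2})

    def test_mean_within_run_range_and_best_marked(self):
        names = ("auroc", "aupr", "precision_at_k", "map", "r_precision")
        rng = np.random.default_rng(5)
        runs = {
            m: [{k: float(rng.uniform(0.4, 0.9)) for k in names}
                for _ in range(3)]
            for m in ("m1", "m2")
        }
        rep = aggregate_runs(runs)
        for m in runs:
            for k in names:
                vals = [r[k] for r in runs[m]]
                assert min(vals) <= rep.mean[m][k] <= max(vals)
        for k in names:
            assert rep.best[k] == max(runs, key=lambda m: rep.mean[m][k])
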