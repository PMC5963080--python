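"""Random walks, the skip-gram trainer contract, and post-processing."""

import numpy as np
import pytest
from scipy import stats

from linkbench.embedding import (
    EmbeddingTable,
    WalkConfig,
    complete_table,
    generate_walks,
    line_postprocess,
    train_embeddings,
)
from linkbench.graph_io import TemporalGraph


def transition_counts(walks, prev, cur):
    """Observed next-step counts over all (prev, cur) occurrences."""
    counts = {}
    for w in walks:
        for i in range(len(w) - 2):
            if w[i] == prev and w[i + 1] == cur:
                counts[w[i + 2]] = counts.get(w[i + 2], 0) + 1
    return counts


class TestGenerateWalks:
    def test_corpus_size_and_lengths(self, triangle):
        cfg = WalkConfig(walk_length=15, walks_per_vertex=4, seed=0)
        walks = generate_walks(triangle, cfg)
        assert len(walks) == 3 * 4
        assert all(len(w) == 15 for w in walks)
        starts = sorted(w[0] for w in walks)
        assert starts == sorted(["a", "b", "c"] * 4)

    def test_isolated_node_yields_length_one_walks(self):
        g = TemporalGraph(nodes={"solo"})
        walks = generate_walks(g, WalkConfig(walks_per_vertex=10, seed=0))
        assert len(walks) == 10
        assert all(w == ["solo"] for w in walks)

    def test_steps_follow_links(self, path_graph):
        walks = generate_walks(path_graph, WalkConfig(walk_length=20, seed=1))
        for w in walks:
            for a, b in zip(w, w[1:]):
                assert path_graph.has_link(a, b)

    def test_uniform_first_step_frequency(self, path_graph):
        # from b the walk steps to a or c with probability 1/2 each
        cfg = WalkConfig(walk_length=2, walks_per_vertex=10_000, seed=2)
        walks = generate_walks(path_graph, cfg)
        from_b = [w[1] for w in walks if w[0] == "b"]
        freq_a = from_b.count("a") / len(from_b)
        assert freq_a == pytest.approx(0.5, abs=0.05)

    def test_biased_triangle_return_probability(self, triangle):
        # prev=a, cur=b: return to a has weight 1/p=1/2, move to c
        # (a neighbour of a) weight 1 -> P(return) = 1/3
        cfg = WalkConfig(walk_length=10, walks_per_vertex=1000, p=2.0, q=4.0,
                         seed=3)
        walks = generate_walks(triangle, cfg, mode="biased")
        counts = transition_counts(walks, "a", "b")
        total = sum(counts.values())
        assert total > 2000
        assert counts.get("a", 0) / total == pytest.approx(1 / 3, abs=0.03)

    def test_biased_q_discounts_unrelated_nodes(self):
        # square a-b-c-d-a: at prev=a, cur=b candidates are a (1/p) and c
        # (not adjacent to a -> 1/q); P(c) = (1/4)/(1/2 + 1/4) = 1/3
        g = TemporalGraph.from_links([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        cfg = WalkConfig(walk_length=12, walks_per_vertex=800, p=2.0, q=4.0,
                         seed=4)
        walks = generate_walks(g, cfg, mode="biased")
        counts = transition_counts(walks, "a", "b")
        total = sum(counts.values())
        assert counts.get("c", 0) / total == pytest.approx(1 / 3, abs=0.03)

    def test_seeded_reproducibility(self, triangle):
        cfg = WalkConfig(seed=7)
        assert generate_walks(triangle, cfg, "biased") == \
            generate_walks(triangle, cfg, "biased")

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            generate_walks(TemporalGraph(), WalkConfig())


class TestTrainerContract:
    def two_cliques(self, size=20):
        links = []
        for block, prefix in ((0, "a"), (1, "b")):
            names = [f"{prefix}{i:02d}" for i in range(size)]
            links += [(x, y) for i, x in enumerate(names) for y in names[i + 1:]]
        return TemporalGraph.from_links(links)

    def test_intra_clique_similarity_exceeds_inter(self):
        g = self.two_cliques()
        cfg = WalkConfig(walk_length=10, walks_per_vertex=5, window=4,
                         dimensions=32, epochs=2, seed=0)
        table = train_embeddings(generate_walks(g, cfg), cfg)
        vecs = {n: v / np.linalg.norm(v) for n, v in table.vectors.items()}
        a = [vecs[n] for n in sorted(vecs) if n.startswith("a")]
        b = [vecs[n] for n in sorted(vecs) if n.startswith("b")]
        intra = np.mean([x @ y for i, x in enumerate(a) for y in a[i + 1:]])
        inter = np.mean([x @ y for x in a for y in b])
        assert intra > inter

    def test_dimension_default_is_100(self, triangle):
        cfg = WalkConfig(walk_length=5, walks_per_vertex=2, epochs=1, seed=0)
        table = train_embeddings(generate_walks(triangle, cfg), cfg)
        assert table.dimension == 100
        assert all(v.shape == (100,) for v in table.vectors.values())

    def test_fixed_seed_is_deterministic(self, triangle, fast_walk_cfg):
        walks = generate_walks(triangle, fast_walk_cfg)
        t1 = train_embeddings(walks, fast_walk_cfg)
        t2 = train_embeddings(walks, fast_walk_cfg)
        for n in t1.vectors:
            assert np.array_equal(t1.vectors[n], t2.vectors[n])

    def test_empty_corpus_rejected(self, fast_walk_cfg):
        with pytest.raises(ValueError):
            train_embeddings([], fast_walk_cfg)


class TestLinePostprocess:
    def table(self, mapping):
        return EmbeddingTable({k: np.array(v, float) for k, v in mapping.items()})

    def test_three_four_five_norm(self):
        out = line_postprocess(self.table({"n": [3, 0]}), self.table({"n": [0, 4]}))
        assert np.allclose(out["n"], [0.6, 0, 0, 0.8])

    def test_output_norm_one_for_nonzero(self):
        first = self.table({"n": [1, 1], "m": [0.2, -0.4]})
        second = self.table({"n": [2, -1], "m": [0.0, 0.1]})
        out = line_postprocess(first, second)
        for v in out.vectors.values():
            assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_zero_vector_passes_through(self):
        out = line_postprocess(self.table({"n": [0, 0]}), self.table({"n": [0, 0]}))
        assert np.array_equal(out["n"], np.zeros(4))

    def test_coverage_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different node sets"):
            line_postprocess(self.table({"n": [1]}), self.table({"m": [1]}))


class TestCompleteTable:
    def test_no_missing_nodes_unchanged(self):
        t = EmbeddingTable({"a": np.ones(4)})
        out = complete_table(t, {"a"}, 4, seed=0)
        assert np.array_equal(out["a"], t["a"])
        assert out.trained_flag["a"] == "trained"

    def test_missing_nodes_flagged_and_reproducible(self):
        t = EmbeddingTable({"a": np.ones(8)})
        missing = {f"m{i}" for i in range(100)}
        out1 = complete_table(t, {"a"} | missing, 8, seed=5)
        out2 = complete_table(t, {"a"} | missing, 8, seed=5)
        assert sum(f == "random-init" for f in out1.trained_flag.values()) == 100
        for n in missing:
            assert np.array_equal(out1[n], out2[n])
            assert np.all(np.abs(out1[n]) <= 0.5 / 8)
        assert out1.random_init_fraction() == pytest.approx(100 / 101)

    def test_word2vec_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        t = EmbeddingTable({f"n{i}": rng.normal(size=6) for i in range(5)})
        path = tmp_path / "emb.txt"
        t.write_word2vec(path)
        back = EmbeddingTable.read_word2vec(path)
        assert set(back.vectors) == set(t.vectors)
        for n in t.vectors:
            assert np.allclose(back[n], t[n], atol=1e-6)
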