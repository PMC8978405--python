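import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import rand_score

from dtlink import (
    SimilarityGraph,
    SkipGramConfig,
    WalkConfig,
    WalkCorpus,
    embed_graph,
    generate_walks,
    train_skipgram,
    transition_distribution,
)


def _unweighted(ids, edges):
    n = len(ids)
    w = np.eye(n)
    for i, j in edges:
        w[i, j] = w[j, i] = 1.0
    return SimilarityGraph(node_ids=ids, weights=w, kind="drug")


class TestTransitionDistribution:
    def test_uniform_when_unbiased(self, triangle_pendant_graph):
        probs = transition_distribution(None, "b", triangle_pendant_graph, p=1, q=1)
        np.testing.assert_allclose(probs, [1 / 3, 0, 1 / 3, 1 / 3])

    @pytest.mark.parametrize("p,q", [(0.25, 4.0), (2.0, 0.5), (1.0, 1.0)])
    def test_normalized_for_any_bias(self, triangle_pendant_graph, p, q):
        probs = transition_distribution("a", "b", triangle_pendant_graph, p=p, q=q)
        assert probs.sum() == pytest.approx(1.0)
        assert (probs >= 0).all()
        assert probs[1] == 0  # no self transition

    def test_triangle_pendant_bias_enumeration(self, triangle_pendant_graph):
        # prev=a, curr=b, p=0.25, q=4: raw weights a: 1/p=4, c: 1 (neighbor
        # of a), d: 1/q=0.25 -> normalized 16/21, 4/21, 1/21
        probs = transition_distribution("a", "b", triangle_pendant_graph, p=0.25, q=4)
        np.testing.assert_allclose(probs, [16 / 21, 0, 4 / 21, 1 / 21])

    def test_isolated_node_rejected(self):
        w = np.eye(2)
        g = SimilarityGraph(["a", "b"], w, "drug")
        with pytest.raises(ValueError, match="neighbor"):
            transition_distribution(None, "a", g, 1, 1)


class TestGenerateWalks:
    def test_walk_count(self):
        g = _unweighted([f"n{i}" for i in range(5)],
                        [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])
        corpus = generate_walks(g, WalkConfig(walks_per_node=2, walk_length=10, seed=0))
        assert len(corpus.walks) == 10

    def test_path_graph_alternates(self):
        g = _unweighted(["a", "b"], [(0, 1)])
        corpus = generate_walks(g, WalkConfig(walks_per_node=1, walk_length=5, seed=0))
        for walk in corpus.walks:
            assert len(walk) == 5
            for k in range(1, 5):
                assert walk[k] != walk[k - 1]

    def test_same_seed_identical_corpus(self, two_clique_graph):
        cfg = WalkConfig(walks_per_node=3, walk_length=20, seed=9)
        c1 = generate_walks(two_clique_graph, cfg)
        c2 = generate_walks(two_clique_graph, cfg)
        assert c1.walks == c2.walks

    def test_walks_only_traverse_positive_edges(self, two_clique_graph):
        corpus = generate_walks(two_clique_graph, WalkConfig(walks_per_node=3, walk_length=30, seed=2))
        idx = {nid: i for i, nid in enumerate(two_clique_graph.node_ids)}
        adj = two_clique_graph.weights
        for walk in corpus.walks:
            for u, v in zip(walk, walk[1:]):
                assert u != v
                assert adj[idx[u], idx[v]] > 0

    def test_step_frequencies_match_transition_distribution(self, triangle_pendant_graph):
        """Empirical (a, b, x) continuation frequencies track the analytic
        second-order distribution within 3-sigma binomial error."""
        p, q = 0.25, 4.0
        corpus = generate_walks(
            triangle_pendant_graph,
            WalkConfig(p=p, q=q, walks_per_node=250, walk_length=60, seed=3),
        )
        counts = {"a": 0, "c": 0, "d": 0}
        total = 0
        for walk in corpus.walks:
            for k in range(2, len(walk)):
                if walk[k - 2] == "a" and walk[k - 1] == "b":
                    counts[walk[k]] += 1
                    total += 1
        assert total > 2000
        probs = transition_distribution("a", "b", triangle_pendant_graph, p, q)
        expected = dict(zip(triangle_pendant_graph.node_ids, probs))
        for node in counts:
            pr = expected[node]
            sigma = np.sqrt(pr * (1 - pr) / total)
            assert abs(counts[node] / total - pr) < 3 * sigma + 1e-9

    def test_stationary_frequency_weight_proportional(self):
        """For p=q=1 the visit frequency of a weighted graph approaches the
        strength-proportional stationary distribution."""
        w = np.eye(3)
        w[0, 1] = w[1, 0] = 0.9
        w[0, 2] = w[2, 0] = 0.3
        w[1, 2] = w[2, 1] = 0.6
        g = SimilarityGraph(["a", "b", "c"], w, "drug")
        corpus = generate_walks(g, WalkConfig(walks_per_node=60, walk_length=200, seed=4))
        visits = {n: 0 for n in g.node_ids}
        total = 0
        for walk in corpus.walks:
            for n in walk[20:]:  # discard burn-in
                visits[n] += 1
                total += 1
        adj = w - np.eye(3)
        strength = adj.sum(axis=1)
        pi = strength / strength.sum()
        for node, expect in zip(g.node_ids, pi):
            assert abs(visits[node] / total - expect) < 0.03

    def test_edgeless_graph_rejected(self):
        g = SimilarityGraph(["a", "b"], np.eye(2), "drug")
        with pytest.raises(ValueError, match="no edges"):
            generate_walks(g, WalkConfig())


class TestTrainSkipgram:
    def _corpus(self, two_clique_graph, seed=1):
        return generate_walks(two_clique_graph, WalkConfig(walks_per_node=5, walk_length=40, seed=seed))

    def test_vector_dimension(self, two_clique_graph):
        emb = train_skipgram(self._corpus(two_clique_graph), SkipGramConfig(dim=100, epochs=1, seed=0))
        assert emb.vectors.shape == (20, 100)

    def test_clique_separation(self, two_clique_graph):
        emb = train_skipgram(self._corpus(two_clique_graph), SkipGramConfig(dim=32, seed=2))
        V = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
        sim = V @ V.T
        block = np.array([0] * 10 + [1] * 10)
        same = block[:, None] == block[None, :]
        off = ~np.eye(20, dtype=bool)
        assert sim[same & off].mean() > sim[~same].mean()

    def test_same_seed_bit_identical(self, two_clique_graph):
        corpus = self._corpus(two_clique_graph)
        cfg = SkipGramConfig(dim=16, seed=5)
        e1 = train_skipgram(corpus, cfg)
        e2 = train_skipgram(corpus, cfg)
        np.testing.assert_array_equal(e1.vectors, e2.vectors)

    def test_loss_decreases_from_first_epoch(self):
        """On a corpus with sharply predictable co-occurrence (disjoint
        edges) the epoch-mean loss drops well past 10% by convergence."""
        n = 20
        w = np.eye(n)
        for i in range(0, n, 2):
            w[i, i + 1] = w[i + 1, i] = 1.0
        g = SimilarityGraph([f"n{i:02d}" for i in range(n)], w, "drug")
        corpus = generate_walks(g, WalkConfig(walks_per_node=3, walk_length=30, seed=1))
        emb = train_skipgram(corpus, SkipGramConfig(dim=16, epochs=8, seed=1))
        losses = emb.training_loss
        assert losses[-1] <= 0.9 * losses[0]

    def test_unobserved_node_rejected(self):
        corpus = WalkCorpus(walks=[["a", "b", "a"]], source="drug")
        with pytest.raises(ValueError, match="never observed"):
            train_skipgram(corpus, SkipGramConfig(dim=4), expected_nodes=["a", "b", "c"])

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_skipgram(WalkCorpus(walks=[], source="drug"), SkipGramConfig(dim=4))


class TestEmbedGraph:
    def test_two_block_partition_recovered(self, two_clique_graph):
        emb = embed_graph(two_clique_graph, WalkConfig(), SkipGramConfig(dim=32), seed=1)
        order = {nid: i for i, nid in enumerate(two_clique_graph.node_ids)}
        truth = np.array([0 if order[n] < 10 else 1 for n in emb.node_ids])
        pred = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(emb.vectors)
        assert rand_score(truth, pred) >= 0.9

    def test_row_per_node(self, two_clique_graph):
        emb = embed_graph(two_clique_graph, WalkConfig(walks_per_node=2, walk_length=10),
                          SkipGramConfig(dim=8, epochs=1), seed=0)
        assert sorted(emb.node_ids) == sorted(two_clique_graph.node_ids)

    def test_insertion_order_invariance(self, two_clique_graph):
        emb1 = embed_graph(two_clique_graph, WalkConfig(walks_per_node=2, walk_length=15),
                           SkipGramConfig(dim=8, epochs=2), seed=3)
        perm = np.random.default_rng(0).permutation(20)
        g2 = SimilarityGraph(
            node_ids=[two_clique_graph.node_ids[i] for i in perm],
            weights=two_clique_graph.weights[np.ix_(perm, perm)],
            kind="drug",
        )
        emb2 = embed_graph(g2, WalkConfig(walks_per_node=2, walk_length=15),
                           SkipGramConfig(dim=8, epochs=2), seed=3)
        for nid in two_clique_graph.node_ids:
            np.testing.assert_array_equal(emb1.vector(nid), emb2.vector(nid))
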