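import numpy as np
import pytest

from dwppi import graph_embed, network
from dwppi.data_io import EdgeRecord
from dwppi.errors import WalkError
from dwppi.graph_embed import EmbeddingMatrix


def g(*edges):
    return network.build_graph([EdgeRecord(a, b) for a, b in edges])


class TestGenerateWalks:
    def test_single_edge_forced_alternation(self):
        graph = g(("a", "b"))
        corpus = graph_embed.generate_walks(graph, 1, 3, seed=0)
        for walk in corpus.walks:
            assert walk in (["a", "b", "a"], ["b", "a", "b"])

    def test_isolated_vertex_singleton_walk(self):
        import networkx as nx

        nxg = nx.Graph()
        nxg.add_edge("a", "b")
        nxg.add_node("c")
        graph = network.ProteinGraph(nxg)
        corpus = graph_embed.generate_walks(graph, 2, 5, seed=0)
        c_walks = [w for w in corpus.walks if w[0] == "c"]
        assert len(c_walks) == 2 and all(w == ["c"] for w in c_walks)

    def test_every_walk_is_a_path(self, small_dataset):
        graph, _, _, _ = small_dataset
        corpus = graph_embed.generate_walks(graph, 2, 10, seed=1)
        for walk in corpus.walks:
            for u, v in zip(walk, walk[1:]):
                assert graph.has_edge(u, v)

    def test_each_vertex_starts_gamma_walks(self, small_dataset):
        graph, _, _, _ = small_dataset
        corpus = graph_embed.generate_walks(graph, 3, 5, seed=1)
        starts = [w[0] for w in corpus.walks]
        assert all(starts.count(v) == 3 for v in graph.vertices)

    def test_first_step_uniform_over_neighbors(self):
        """Binomial oracle: on a triangle each neighbor is the first step
        with frequency 1/2 within 3 sigma."""
        graph = g(("a", "b"), ("b", "c"), ("a", "c"))
        n = 10_000
        corpus = graph_embed.generate_walks(graph, n // 3 + 1, 2, seed=2)
        from_a = [w[1] for w in corpus.walks if w[0] == "a"]
        m = len(from_a)
        freq = from_a.count("b") / m
        bound = 3 * np.sqrt(0.25 / m)
        assert abs(freq - 0.5) <= bound

    def test_invalid_length_raises(self):
        with pytest.raises(WalkError):
            graph_embed.generate_walks(g(("a", "b")), 1, 0, seed=0)


class TestTrainSkipgram:
    def test_seed_determinism(self, small_dataset, fast_config):
        graph, _, _, _ = small_dataset
        corpus = graph_embed.generate_walks(graph, 2, 8, seed=3)
        kw = dict(window=3, sigma=8, epochs=2, learning_rate=0.05, seed=11)
        e1 = graph_embed.train_skipgram(corpus, **kw)
        e2 = graph_embed.train_skipgram(corpus, **kw)
        assert np.array_equal(e1.vectors, e2.vectors)

    def test_sigma_row_dimension(self, small_dataset):
        graph, _, _, _ = small_dataset
        corpus = graph_embed.generate_walks(graph, 1, 8, seed=3)
        emb = graph_embed.train_skipgram(corpus, 3, 64, 1, 0.05, seed=1)
        assert emb.vectors.shape == (graph.n_vertices, 64)

    def test_clique_separation(self):
        """Two 10-cliques joined by a bridge: within-clique similarity must
        exceed between-clique similarity after training."""
        edges = []
        for base in ("x", "y"):
            ids = [f"{base}{i}" for i in range(10)]
            edges += [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
        edges.append(("x0", "y0"))
        graph = g(*edges)
        corpus = graph_embed.generate_walks(graph, 10, 20, seed=4)
        emb = graph_embed.train_skipgram(corpus, 5, 16, 5, 0.05, seed=4)
        sim = graph_embed.cosine_similarity_matrix(emb)
        idx = {v: i for i, v in enumerate(emb.vocabulary)}
        xs = [idx[f"x{i}"] for i in range(10)]
        ys = [idx[f"y{i}"] for i in range(10)]
        within = np.mean([sim[i, j] for i in xs for j in xs if i != j]
                         + [sim[i, j] for i in ys for j in ys if i != j])
        between = np.mean([sim[i, j] for i in xs for j in ys])
        assert within > between


class TestCosineSimilarity:
    def test_closed_forms(self):
        emb = EmbeddingMatrix(["a", "b", "c"], np.array([[1.0, 0], [0, 1], [1, 1]]))
        sim = graph_embed.cosine_similarity_matrix(emb)
        assert sim[0, 0] == pytest.approx(1.0)
        assert sim[0, 1] == pytest.approx(0.0)
        assert sim[0, 2] == pytest.approx(1 / np.sqrt(2))

    def test_symmetry_and_range(self, rng):
        emb = EmbeddingMatrix([f"v{i}" for i in range(12)], rng.normal(size=(12, 6)))
        sim = graph_embed.cosine_similarity_matrix(emb)
        assert np.allclose(sim, sim.T)
        assert np.all(sim >= -1) and np.all(sim <= 1)
        assert np.allclose(np.diag(sim), 1.0)

    def test_zero_row_policy(self):
        emb = EmbeddingMatrix(["a", "b"], np.array([[0.0, 0.0], [1.0, 2.0]]))
        sim = graph_embed.cosine_similarity_matrix(emb)
        assert sim[0, 0] == 0.0 and sim[0, 1] == 0.0


class TestEmbeddingTsv:
    def test_round_trip(self, rng, tmp_path):
        emb = EmbeddingMatrix([f"v{i}" for i in range(5)], rng.normal(size=(5, 4)))
        p = tmp_path / "emb.tsv"
        emb.to_tsv(p)
        back = EmbeddingMatrix.from_tsv(p)
        assert back.vocabulary == emb.vocabulary
        assert np.array_equal(back.vectors, emb.vectors)
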