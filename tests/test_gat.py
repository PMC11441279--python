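"""Heterogeneous graph construction and the attention autoencoder."""

import numpy as np
import pytest

from circdrug import (
    AssociationMatrix,
    GATConfig,
    build_hetero_graph,
    train_gat_autoencoder,
)
from circdrug.autograd import Tensor
from circdrug.gat import attention_layer
from circdrug.nn import Linear
from circdrug.similarity import SimilarityKind, SimilarityMatrix


def small_graph(n=12, m=8, seed=0, k_sim=2):
    rng = np.random.default_rng(seed)
    values = (rng.random((n, m)) < 0.3).astype(int)
    values[0, 0] = 1
    A = AssociationMatrix(
        values, tuple(f"c{i}" for i in range(n)), tuple(f"d{j}" for j in range(m))
    )
    W = rng.random((n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 1.0)
    sm = SimilarityMatrix(W, A.circ_ids, SimilarityKind.fused)
    return build_hetero_graph(sm, A, k_sim=k_sim), A, sm


FAST = GATConfig(heads=2, head_dim_layer1=8, out_dim=6, epochs=15, seed=0)


class TestBuildHeteroGraph:
    def test_feature_block_structure(self):
        graph, A, sm = small_graph()
        n, m = A.n_circ, A.n_drug
        assert graph.features.shape == (n + m, n + m)
        np.testing.assert_array_equal(graph.features[:n, :n], sm.values)
        np.testing.assert_array_equal(graph.features[:n, n:], A.values)
        np.testing.assert_array_equal(graph.features[n:, :n], A.values.T)
        assert (graph.features[n:, n:] == 0).all()

    def test_adjacency_symmetric_with_self_loops(self):
        graph, A, _ = small_graph()
        adj = graph.adjacency
        np.testing.assert_array_equal(adj, adj.T)
        assert (np.diag(adj) == 1).all()

    def test_drug_drug_block_has_only_self_loops(self):
        graph, A, _ = small_graph()
        n = A.n_circ
        dd = graph.adjacency[n:, n:]
        np.testing.assert_array_equal(dd, np.eye(A.n_drug, dtype=int))


class TestAttentionLayer:
    def _layer(self, n_nodes=9, n_feat=5, head_dim=4, heads=2, seed=1):
        rng = np.random.default_rng(seed)
        adj = (rng.random((n_nodes, n_nodes)) < 0.4).astype(int)
        adj = ((adj + adj.T) > 0).astype(int)
        np.fill_diagonal(adj, 1)
        H = Tensor(rng.standard_normal((n_nodes, n_feat)))
        Ws = [Linear(n_feat, head_dim, rng) for _ in range(heads)]
        a_s = [Tensor(rng.standard_normal((head_dim, 1))) for _ in range(heads)]
        a_d = [Tensor(rng.standard_normal((head_dim, 1))) for _ in range(heads)]
        return H, adj, Ws, a_s, a_d

    def test_attention_rows_sum_to_one(self):
        H, adj, Ws, a_s, a_d = self._layer()
        _, alphas = attention_layer(H, adj, Ws, a_s, a_d, 0.2, "concat")
        for alpha in alphas:
            np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
            assert (alpha[adj == 0] == 0).all()

    def test_single_neighbour_gets_unit_attention(self):
        H, _, Ws, a_s, a_d = self._layer()
        adj = np.eye(9, dtype=int)
        adj[0, 1] = 0  # node 0's only neighbour is itself
        _, alphas = attention_layer(H, adj, Ws, a_s, a_d, 0.2, "concat")
        for alpha in alphas:
            assert alpha[0, 0] == pytest.approx(1.0)

    def test_concat_width_is_heads_times_dim(self):
        H, adj, Ws, a_s, a_d = self._layer(head_dim=4, heads=2)
        out, _ = attention_layer(H, adj, Ws, a_s, a_d, 0.2, "concat")
        assert out.data.shape[1] == 8
        out_mean, _ = attention_layer(H, adj, Ws, a_s, a_d, 0.2, "mean")
        assert out_mean.data.shape[1] == 4

    def test_default_settings_give_192_wide_first_layer(self):
        rng = np.random.default_rng(0)
        H = Tensor(rng.standard_normal((10, 20)))
        adj = np.eye(10, dtype=int)
        Ws = [Linear(20, 64, rng) for _ in range(3)]
        a_s = [Tensor(rng.standard_normal((64, 1))) for _ in range(3)]
        a_d = [Tensor(rng.standard_normal((64, 1))) for _ in range(3)]
        out, _ = attention_layer(H, adj, Ws, a_s, a_d, 0.2, "concat")
        assert out.data.shape[1] == 3 * 64


class TestTrainGAT:
    def test_output_shape_is_circ_by_out_dim(self):
        graph, A, _ = small_graph()
        emb, history = train_gat_autoencoder(graph, FAST)
        assert emb.values.shape == (A.n_circ, FAST.out_dim)
        assert len(history) == FAST.epochs

    def test_deterministic_under_seed(self):
        graph, _, _ = small_graph()
        a, ha = train_gat_autoencoder(graph, FAST)
        b, hb = train_gat_autoencoder(graph, FAST)
        np.testing.assert_array_equal(a.values, b.values)
        assert ha == hb

    def test_reconstruction_loss_decreases(self):
        graph, _, _ = small_graph()
        _, history = train_gat_autoencoder(graph, FAST)
        assert history[-1] < history[0]

    def test_attention_normalized_every_epoch(self):
        graph, _, _ = small_graph()
        seen = []

        def on_epoch(epoch, loss, alphas):
            for alpha in alphas:
                np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
            seen.append(epoch)

        train_gat_autoencoder(graph, FAST, on_epoch=on_epoch)
        assert len(seen) == FAST.epochs

    def test_attention_layer_permutation_equivariance(self):
        """With fixed weights, permuting node rows and the adjacency permutes
        the layer output identically (node features treated as attributes)."""
        rng = np.random.default_rng(5)
        n_nodes, n_feat = 20, 7
        adj = (rng.random((n_nodes, n_nodes)) < 0.3).astype(int)
        adj = ((adj + adj.T) > 0).astype(int)
        np.fill_diagonal(adj, 1)
        H = rng.standard_normal((n_nodes, n_feat))
        Ws = [Linear(n_feat, 5, rng) for _ in range(2)]
        a_s = [Tensor(rng.standard_normal((5, 1))) for _ in range(2)]
        a_d = [Tensor(rng.standard_normal((5, 1))) for _ in range(2)]

        out, _ = attention_layer(Tensor(H), adj, Ws, a_s, a_d, 0.2, "concat")
        perm = rng.permutation(n_nodes)
        out_p, _ = attention_layer(
            Tensor(H[perm]), adj[np.ix_(perm, perm)], Ws, a_s, a_d, 0.2, "concat"
        )
        np.testing.assert_allclose(out_p.data, out.data[perm], atol=1e-10)

    def test_planted_communities_separate_in_embedding_space(self):
        """Two circRNA blocks attached to disjoint drug sets must come out
        more similar within blocks than across."""
        n, m = 20, 10
        values = np.zeros((n, m), dtype=int)
        values[:10, :5] = 1
        values[10:, 5:] = 1
        A = AssociationMatrix(
            values, tuple(f"c{i}" for i in range(n)), tuple(f"d{j}" for j in range(m))
        )
        W = np.full((n, n), 0.1)
        W[:10, :10] = 0.8
        W[10:, 10:] = 0.8
        np.fill_diagonal(W, 1.0)
        sm = SimilarityMatrix(W, A.circ_ids, SimilarityKind.fused)
        graph = build_hetero_graph(sm, A, k_sim=3)
        emb, _ = train_gat_autoencoder(
            graph, GATConfig(heads=2, head_dim_layer1=8, out_dim=8, epochs=60, seed=0)
        )
        Z = emb.values / np.linalg.norm(emb.values, axis=1, keepdims=True)
        cos = Z @ Z.T
        block = np.zeros((n, n), dtype=bool)
        block[:10, :10] = block[10:, 10:] = True
        np.fill_diagonal(block, False)
        within = cos[block].mean()
        between = cos[~block & ~np.eye(n, dtype=bool)].mean()
        assert within > between
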