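"""Multi-head graph-attention autoencoder for circRNA embeddings.

The heterogeneous graph puts the N circRNA nodes first and the M drug nodes
after them.  Node features are the block matrix

    X = [[SM', A ],
         [A^T, 0 ]]

(fused circRNA similarity, association matrix, and a zero drug-drug block).
Edges are: circRNA-drug association edges, circRNA-circRNA edges between each
circRNA and its top-k fused-similarity neighbours (symmetrized), and
self-loops on every node.  A two-layer multi-head attention encoder (heads
concatenated at layer 1 with ELU, averaged at layer 2) produces 128-dim node
embeddings Z, trained to reconstruct the adjacency through an inner-product
decoder sigmoid(Z Z^T) under binary cross entropy.  The first N rows of Z are
the circRNA embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, bce_with_logits, concat, masked_softmax
from .datasets import AssociationMatrix
from .embeddings import EmbeddingMatrix, EmbeddingSource
from .errors import ConfigurationError, DimensionError, TrainingError
from .nn import Adam, Linear, one_cycle_lr
from .similarity import SimilarityMatrix

__all__ = ["HeteroGraph", "GATConfig", "build_hetero_graph", "attention_layer", "train_gat_autoencoder"]


@dataclass(frozen=True)
class HeteroGraph:
    """Feature matrix, adjacency and node bookkeeping for the joint graph."""

    features: np.ndarray  # (N+M, N+M)
    adjacency: np.ndarray  # binary, symmetric, self-loops
    n_circ: int
    n_drug: int
    circ_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]


@dataclass(frozen=True)
class GATConfig:
    heads: int = 3
    head_dim_layer1: int = 64
    out_dim: int = 128
    weight_decay: float = 5e-3
    lr_max: float = 1e-3
    epochs: int = 300
    negative_slope: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heads < 1:
            raise ConfigurationError("heads must be >= 1")
        if self.out_dim < 1:
            raise ConfigurationError("out_dim must be >= 1")


def build_hetero_graph(
    SM_prime: SimilarityMatrix, A: AssociationMatrix, k_sim: int | None = None
) -> HeteroGraph:
    """Assemble block features and adjacency (associations + top-k similarity)."""
    if SM_prime.ids != A.circ_ids:
        raise DimensionError("circRNA ids of similarity network and association matrix differ")
    n, m = A.n_circ, A.n_drug
    if k_sim is None:
        k_sim = max(1, n // 10)
    if not 1 <= k_sim < n:
        raise ConfigurationError(f"k_sim must satisfy 1 <= k_sim < {n}")

    X = np.zeros((n + m, n + m))
    X[:n, :n] = SM_prime.values
    X[:n, n:] = A.values
    X[n:, :n] = A.values.T

    adj = np.zeros((n + m, n + m), dtype=np.int64)
    adj[:n, n:] = A.values
    adj[n:, :n] = A.values.T
    sim = SM_prime.values.copy()
    np.fill_diagonal(sim, -np.inf)
    for i in range(n):
        nbrs = np.argsort(-sim[i], kind="stable")[:k_sim]
        adj[i, nbrs] = 1
        adj[nbrs, i] = 1
    np.fill_diagonal(adj, 1)
    return HeteroGraph(
        features=X,
        adjacency=adj,
        n_circ=n,
        n_drug=m,
        circ_ids=A.circ_ids,
        drug_ids=A.drug_ids,
    )


def attention_layer(
    H_in: Tensor,
    adjacency: np.ndarray,
    weights: list[Linear],
    attn_src: list[Tensor],
    attn_dst: list[Tensor],
    negative_slope: float,
    combine: str,
) -> tuple[Tensor, list[np.ndarray]]:
    """One multi-head attention layer over the fixed edge set.

    Per head: project ``H = X W``; score every edge (i, j) with
    ``LeakyReLU(a^T [h_i || h_j])`` (split as ``a_src . h_i + a_dst . h_j``);
    softmax the scores over each node's neighbourhood; aggregate neighbour
    projections.  Heads are concatenated (``combine="concat"``) or averaged
    (``combine="mean"``).  Returns the combined output and each head's dense
    attention matrix (rows summing to 1 over neighbours).
    """
    outputs = []
    alphas = []
    for W, a_s, a_d in zip(weights, attn_src, attn_dst):
        H = W(H_in)
        s_src = H @ a_s  # (n, 1)
        s_dst = H @ a_d
        E = (s_src + s_dst.T).leaky_relu(negative_slope)
        alpha = masked_softmax(E, adjacency)
        outputs.append(alpha @ H)
        alphas.append(alpha.data)
    if combine == "concat":
        out = concat(outputs, axis=1)
    elif combine == "mean":
        out = outputs[0]
        for o in outputs[1:]:
            out = out + o
        out = out * (1.0 / len(outputs))
    else:
        raise ConfigurationError(f"unknown combine mode {combine!r}")
    return out, alphas


class _GATEncoder:
    def __init__(self, n_features: int, config: GATConfig, rng: np.random.Generator):
        c = config
        self.config = c
        self.W1 = [Linear(n_features, c.head_dim_layer1, rng) for _ in range(c.heads)]
        self.a1_src = [Tensor(rng.normal(0, 0.1, (c.head_dim_layer1, 1))) for _ in range(c.heads)]
        self.a1_dst = [Tensor(rng.normal(0, 0.1, (c.head_dim_layer1, 1))) for _ in range(c.heads)]
        d1 = c.heads * c.head_dim_layer1
        self.W2 = [Linear(d1, c.out_dim, rng) for _ in range(c.heads)]
        self.a2_src = [Tensor(rng.normal(0, 0.1, (c.out_dim, 1))) for _ in range(c.heads)]
        self.a2_dst = [Tensor(rng.normal(0, 0.1, (c.out_dim, 1))) for _ in range(c.heads)]

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layer in self.W1 + self.W2:
            ps.extend(layer.params)
        ps.extend(self.a1_src + self.a1_dst + self.a2_src + self.a2_dst)
        return ps

    def forward(self, X: np.ndarray, adj: np.ndarray) -> tuple[Tensor, list[np.ndarray]]:
        c = self.config
        h1, alphas1 = attention_layer(
            Tensor(X), adj, self.W1, self.a1_src, self.a1_dst, c.negative_slope, "concat"
        )
        h1 = h1.elu()
        z, alphas2 = attention_layer(
            h1, adj, self.W2, self.a2_src, self.a2_dst, c.negative_slope, "mean"
        )
        return z, alphas1 + alphas2


def train_gat_autoencoder(
    graph: HeteroGraph,
    config: GATConfig = GATConfig(),
    on_epoch=None,
) -> tuple[EmbeddingMatrix, list[float]]:
    """Train the attention autoencoder; returns circRNA embeddings and loss history.

    ``on_epoch(epoch, loss, alphas)`` is called once per epoch with every
    head's dense attention matrix, for diagnostics.
    """
    rng = np.random.default_rng(config.seed)
    enc = _GATEncoder(graph.features.shape[1], config, rng)
    opt = Adam(enc.params, lr=config.lr_max, weight_decay=config.weight_decay)
    target = graph.adjacency.astype(np.float64)

    history: list[float] = []
    for epoch in range(config.epochs):
        opt.lr = one_cycle_lr(epoch, config.epochs, config.lr_max)
        z, alphas = enc.forward(graph.features, graph.adjacency)
        logits = z @ z.T
        loss = bce_with_logits(logits, target).mean()
        if not np.isfinite(loss.data):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss.data))
        if on_epoch is not None:
            on_epoch(epoch, float(loss.data), alphas)

    z, _ = enc.forward(graph.features, graph.adjacency)
    emb = EmbeddingMatrix(
        values=z.data[: graph.n_circ],
        ids=graph.circ_ids,
        source=EmbeddingSource.gat,
    )
    return emb, history
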