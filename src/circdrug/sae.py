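"""Sparse-autoencoder extraction of 128-dimensional drug embeddings.

Each drug is described by the concatenation of its row in the fused drug
similarity network and its association profile over circRNAs (values in
[0, 1]).  A symmetric encoder/decoder stack (hidden widths 400, 350, 256, 128
by default, rectifier activations, logistic output) is trained to reconstruct
that description under binary cross entropy; a sparsity penalty pulls the
per-unit batch-mean activation of the 128-unit coding layer toward a small
target ``beta``.  The coding-layer activations are the drug embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, bce_with_logits
from .datasets import AssociationMatrix
from .embeddings import EmbeddingMatrix, EmbeddingSource
from .errors import ConfigurationError, DimensionError, TrainingError
from .nn import Adam, Linear
from .similarity import SimilarityMatrix

__all__ = ["SAEConfig", "build_drug_inputs", "train_sae"]


@dataclass(frozen=True)
class SAEConfig:
    encoder_sizes: tuple[int, ...] = (400, 350, 256, 128)
    decoder_sizes: tuple[int, ...] = (128, 256, 350, 400)
    sparsity_weight: float = 1e-3  # alpha
    sparsity_target: float = 0.05  # beta
    epochs: int = 50
    batch_size: int = 128
    lr: float = 1e-3
    seed: int = 0
    similarity_only_input: bool = False
    literal_weight_penalty: bool = False

    def __post_init__(self) -> None:
        if self.encoder_sizes[-1] != self.decoder_sizes[0]:
            raise ConfigurationError("last encoder size must equal first decoder size")
        if self.sparsity_weight < 0:
            raise ConfigurationError("sparsity_weight must be >= 0")
        if not 0 < self.sparsity_target < 1:
            raise ConfigurationError("sparsity_target must lie in (0, 1)")


def build_drug_inputs(
    SD_prime: SimilarityMatrix, A: AssociationMatrix, similarity_only: bool = False
) -> np.ndarray:
    """Per-drug input rows: fused similarity row concatenated with A^T row."""
    if SD_prime.ids != A.drug_ids:
        raise DimensionError("drug ids of similarity network and association matrix differ")
    sim = SD_prime.values
    if similarity_only:
        inputs = sim.copy()
    else:
        inputs = np.concatenate([sim, A.values.T.astype(np.float64)], axis=1)
    return np.clip(inputs, 0.0, 1.0)


def train_sae(
    inputs: np.ndarray, config: SAEConfig, ids: tuple[str, ...] | None = None
) -> tuple[EmbeddingMatrix, list[dict[str, float]]]:
    """Train the sparse autoencoder; returns embeddings and per-epoch losses.

    The logged history has keys ``recon``, ``sparse`` and ``total`` with
    ``total == recon + sparse``.  Reconstruction loss is the per-drug sum of
    binary cross entropy over input features, averaged over the batch.
    """
    X = np.asarray(inputs, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DimensionError("inputs must be a 2-D matrix with at least 2 rows")
    if X.min() < 0 or X.max() > 1:
        raise DimensionError("inputs must lie in [0, 1]")
    n, width = X.shape
    if ids is None:
        ids = tuple(f"drug{i}" for i in range(n))

    rng = np.random.default_rng(config.seed)
    sizes = [width, *config.encoder_sizes, *config.decoder_sizes[1:], width]
    layers = [Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
    n_enc = len(config.encoder_sizes)
    params = [p for layer in layers for p in layer.params]
    opt = Adam(params, lr=config.lr)

    alpha = config.sparsity_weight
    beta = config.sparsity_target

    def forward(batch: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        h = Tensor(batch)
        code = None
        for li, layer in enumerate(layers):
            h = layer(h)
            if li < len(layers) - 1:
                h = h.relu()
            if li == n_enc - 1:
                code = h
        recon = bce_with_logits(h, batch).row_sum_mean()
        if alpha == 0.0:
            sparse = Tensor(0.0)
        elif config.literal_weight_penalty:
            # literal reading: MSE of the coding layer's weight tensor toward beta
            W = layers[n_enc - 1].W
            sparse = alpha * ((W - beta) ** 2).mean()
        else:
            mean_act = code.mean(axis=0)
            sparse = alpha * ((mean_act - beta) ** 2).mean()
        return recon, sparse, code

    history: list[dict[str, float]] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        recon_sum = sparse_sum = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch = X[order[start : start + config.batch_size]]
            recon, sparse, _ = forward(batch)
            total = recon + sparse
            if not np.isfinite(total.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            total.backward()
            opt.step()
            recon_sum += float(recon.data)
            sparse_sum += float(sparse.data)
            n_batches += 1
        rec, spa = recon_sum / n_batches, sparse_sum / n_batches
        history.append({"recon": rec, "sparse": spa, "total": rec + spa})

    _, _, code = forward(X)
    embedding = EmbeddingMatrix(values=code.data, ids=ids, source=EmbeddingSource.sae)
    return embedding, history
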