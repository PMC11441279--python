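"""Nonlinear similarity-network fusion by iterative cross-diffusion.

Three per-entity similarity networks are integrated into one comprehensive
network: each network is (i) row-normalized with the diagonal pinned at 1/2,
(ii) reduced to a KNN local-affinity transition matrix, then (iii) iteratively
updated by diffusing the average of the *other* networks through its own KNN
matrix, renormalizing after every step.  The iterate average is symmetrized to
give the fused network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DimensionError, NormalizationError
from .similarity import SimilarityKind, SimilarityMatrix

__all__ = [
    "FusionConfig",
    "FusionResult",
    "default_k",
    "normalize_full",
    "knn_affinity",
    "fuse",
]


def default_k(n_entities: int) -> int:
    """Default KNN size: one tenth of the entity count, rounded down."""
    return max(1, n_entities // 10)


@dataclass(frozen=True)
class FusionConfig:
    k_neighbors: int
    tol: float = 1e-6
    max_iter: int = 20
    d: int = 3

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")
        if self.tol <= 0:
            raise ConfigurationError("tol must be positive")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")


@dataclass(frozen=True)
class FusionResult:
    fused: SimilarityMatrix
    iterations_run: int
    final_relative_change: float
    converged: bool
    relative_changes: tuple[float, ...] = field(default=())


def _as_array(W: SimilarityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(W, SimilarityMatrix):
        return np.asarray(W.values, dtype=np.float64)
    return np.asarray(W, dtype=np.float64)


def normalize_full(W: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Row normalization with the diagonal pinned at 1/2.

    Off-diagonal entries become ``W_ij / (2 * sum_{k != i} W_ik)`` so that each
    row sums to exactly 1.
    """
    W = _as_array(W)
    n = W.shape[0]
    if W.ndim != 2 or W.shape[1] != n:
        raise DimensionError("normalize_full expects a square matrix")
    off_sums = W.sum(axis=1) - np.diag(W)
    bad = np.nonzero(off_sums <= 0)[0]
    if bad.size:
        raise NormalizationError(
            f"row {bad[0]} has no positive off-diagonal entries"
        )
    out = W / (2.0 * off_sums[:, None])
    np.fill_diagonal(out, 0.5)
    return out


def knn_affinity(W: SimilarityMatrix | np.ndarray, K: int) -> np.ndarray:
    """Row-stochastic local affinity restricted to each row's K nearest neighbours.

    Self is excluded from the neighbour set; ties are broken toward the smaller
    column index for determinism.
    """
    W = _as_array(W)
    n = W.shape[0]
    if not 1 <= K < n:
        raise ConfigurationError(f"K must satisfy 1 <= K < {n}, got {K}")
    out = np.zeros_like(W)
    for i in range(n):
        row = W[i].copy()
        row[i] = -np.inf  # exclude self
        order = np.argsort(-row, kind="stable")  # stable: ties -> smaller index
        nbrs = order[:K]
        mass = W[i, nbrs].sum()
        if mass > 0:
            out[i, nbrs] = W[i, nbrs] / mass
    return out


def fuse(
    networks: Sequence[SimilarityMatrix], config: FusionConfig
) -> FusionResult:
    """Cross-diffusion fusion of ``d`` similarity networks sharing one id list."""
    if len(networks) != config.d:
        raise DimensionError(f"expected {config.d} networks, got {len(networks)}")
    ids = networks[0].ids
    for net in networks[1:]:
        if net.ids != ids:
            raise DimensionError("networks do not share an identifier list")
    d = config.d
    S = [knn_affinity(net, config.k_neighbors) for net in networks]
    P = [normalize_full(net) for net in networks]

    changes: list[float] = []
    converged = False
    iterations = 0
    for _ in range(config.max_iter):
        iterations += 1
        new_P = []
        for v in range(d):
            others = sum(P[u] for u in range(d) if u != v) / (d - 1)
            updated = S[v] @ others @ S[v].T
            new_P.append(normalize_full(updated))
        rel = max(
            np.linalg.norm(new_P[v] - P[v]) / np.linalg.norm(P[v]) for v in range(d)
        )
        changes.append(float(rel))
        P = new_P
        if rel < config.tol:
            converged = True
            break

    SM = sum(P) / d
    SM_sym = (SM + SM.T) / 2.0
    fused = SimilarityMatrix(
        values=np.clip(SM_sym, 0.0, 1.0), ids=ids, kind=SimilarityKind.fused
    )
    return FusionResult(
        fused=fused,
        iterations_run=iterations,
        final_relative_change=changes[-1],
        converged=converged,
        relative_changes=tuple(changes),
    )
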