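"""Masked, L2-regularized non-negative matrix factorization.

The association matrix ``C`` (circRNAs x drugs) is factorized as ``C ~ U V``
with ``U`` (N x k) and ``V`` (k x M) non-negative, minimizing

    || W . (C - U V) ||_F^2 + lambda1 ||U||_F^2 + lambda2 ||V||_F^2

where the mask ``W`` equals the association matrix itself: only known positive
cells constrain the reconstruction, and the regularization terms control the
rest.  Optimization uses multiplicative updates with a constant ``(lambda/2)``
term added to the denominators and a small epsilon guard against division by
zero; exactly ``iterations`` updates are performed, no early stopping.

A note on the recorded objective: a constant additive denominator term is the
multiplicative-update treatment of an *L1* penalty — the updates monotonically
descend ``||W . (C - UV)||_F^2 + lambda1*sum(U) + lambda2*sum(V)``, not the
Frobenius-penalized form above (which can drift upward by ~1e-4 near
convergence).  ``objective_history`` therefore records the descent objective;
``nmf_objective`` evaluates the Frobenius-penalized form for external use.
With ``lambda = 0`` the two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, ConfigurationError

__all__ = ["NMFConfig", "FactorPair", "nmf_objective", "nmf_descent_objective", "nmf_factorize"]


@dataclass(frozen=True)
class NMFConfig:
    k: int = 128
    lambda1: float = 0.01
    lambda2: float = 0.01
    iterations: int = 500
    eps: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ConfigurationError("regularization coefficients must be >= 0")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")


@dataclass(frozen=True)
class FactorPair:
    """Factor matrices: U (N x k) and V stored transposed as (M x k)."""

    U: np.ndarray
    V_t: np.ndarray
    objective_history: tuple[float, ...]


def nmf_objective(
    C: np.ndarray,
    W: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    lambda1: float,
    lambda2: float,
) -> float:
    """Masked squared-residual objective with Tikhonov penalties."""
    C = np.asarray(C, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if (C < 0).any() or (W < 0).any() or (U < 0).any() or (V < 0).any():
        raise ComputationError("nmf_objective requires non-negative inputs")
    resid = W * (C - U @ V)
    return float(
        (resid**2).sum() + lambda1 * (U**2).sum() + lambda2 * (V**2).sum()
    )


def nmf_descent_objective(
    C: np.ndarray,
    W: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    lambda1: float,
    lambda2: float,
) -> float:
    """The objective the multiplicative updates monotonically decrease.

    Masked squared residual plus L1 penalties (see module docstring)."""
    resid = np.asarray(W, dtype=np.float64) * (np.asarray(C, dtype=np.float64) - U @ V)
    return float((resid**2).sum() + lambda1 * U.sum() + lambda2 * V.sum())


def nmf_factorize(
    C: np.ndarray, W: np.ndarray | None = None, config: NMFConfig = NMFConfig()
) -> FactorPair:
    """Run the multiplicative updates for exactly ``config.iterations`` steps.

    ``U <- U . [(W.C) V^T] / [(W.(UV)) V^T + (lambda1/2) J + eps]`` and the
    symmetric update for ``V``; factors are initialized Uniform(0, 1) under the
    config seed.  The objective after every iteration is recorded.
    """
    C = np.asarray(C, dtype=np.float64)
    if (C < 0).any():
        raise ComputationError("C must be non-negative")
    W = C.copy() if W is None else np.asarray(W, dtype=np.float64)
    n, m = C.shape
    if config.k > min(n, m):
        raise ConfigurationError(
            f"k={config.k} exceeds min(N, M)={min(n, m)}"
        )
    rng = np.random.default_rng(config.seed)
    U = rng.random((n, config.k))
    V = rng.random((config.k, m))
    WC = W * C
    half1 = config.lambda1 / 2.0
    half2 = config.lambda2 / 2.0
    history = []
    for _ in range(config.iterations):
        WUV = W * (U @ V)
        U = U * (WC @ V.T) / (WUV @ V.T + half1 + config.eps)
        WUV = W * (U @ V)
        V = V * (U.T @ WC) / (U.T @ WUV + half2 + config.eps)
        history.append(
            nmf_descent_objective(C, W, U, V, config.lambda1, config.lambda2)
        )
    return FactorPair(U=U, V_t=V.T.copy(), objective_history=tuple(history))
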