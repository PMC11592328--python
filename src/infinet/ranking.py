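"""Matrix-free Google operator, PageRank/CheiRank, and rank indices.

The Google matrix is G = alpha * S + (1 - alpha)/N, where S is the
column-stochastic transition matrix (dangling columns uniform) and
alpha = 0.85 is the usual damping factor.  PageRank P is the stationary
vector G P = P; CheiRank P* is the PageRank of the link-inverted network.
The rank index K orders nodes by decreasing probability (K = 1 for the
largest), with ties broken by ascending node index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from infinet.network import (
    DirectedNetwork,
    TransitionMatrices,
    build_transition_matrices,
    invert_network,
)


class PowerIterationError(RuntimeError):
    """Power iteration failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class GoogleOperator:
    """The damped random-surfer operator, applied matrix-free."""

    matrices: TransitionMatrices
    alpha: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"damping factor alpha={self.alpha} outside [0, 1]")

    @property
    def N(self) -> int:
        return self.matrices.N

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return apply_google(self, v)


def apply_google(op: GoogleOperator, v: np.ndarray) -> np.ndarray:
    """Return G v = alpha * S v + (1 - alpha)/N * sum(v).

    Never materializes a dense N x N matrix; preserves the element sum
    of ``v`` (for a probability vector the sum stays 1).
    """
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (op.N,):
        raise ValueError(f"vector has shape {v.shape}, expected ({op.N},)")
    return op.alpha * op.matrices.s_matvec(v) + (1.0 - op.alpha) * v.sum() / op.N


@dataclass
class RankVector:
    """Per-node stationary probabilities and their descending-rank index."""

    probabilities: np.ndarray
    rank_index: np.ndarray  # per-node 1-based rank K (or K*)
    kind: str  # "pagerank" | "cheirank"
    residual: float

    def top(self, k: int) -> np.ndarray:
        """Node indices of the k best-ranked nodes (rank 1 first)."""
        order = np.argsort(self.rank_index)
        return order[:k]


def rank_index(P: np.ndarray) -> np.ndarray:
    """1-based descending rank of each entry; ties by ascending index.

    rank 1 = largest probability; the result is a bijection onto 1..N.
    """
    P = np.asarray(P, dtype=np.float64)
    if not np.all(np.isfinite(P)):
        raise ValueError("rank_index requires finite values")
    order = np.lexsort((np.arange(P.size), -P))
    ranks = np.empty(P.size, dtype=np.int64)
    ranks[order] = np.arange(1, P.size + 1)
    return ranks


def pagerank(
    op: GoogleOperator, tol: float = 1e-12, max_iter: int = 10_000
) -> RankVector:
    """Power iteration from the uniform vector until the L1 change < tol."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    v = np.full(op.N, 1.0 / op.N)
    residual = np.inf
    for _ in range(max_iter):
        w = apply_google(op, v)
        residual = float(np.abs(w - v).sum())
        v = w
        if residual < tol:
            break
    else:
        raise PowerIterationError(
            f"pagerank did not converge in {max_iter} iterations "
            f"(last L1 residual {residual:.3e})",
            residual,
        )
    return RankVector(
        probabilities=v, rank_index=rank_index(v), kind="pagerank", residual=residual
    )


def cheirank(
    net: DirectedNetwork,
    alpha: float = 0.85,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> RankVector:
    """PageRank of the link-inverted network (communicativity ranking)."""
    tm_inv = build_transition_matrices(invert_network(net))
    rv = pagerank(GoogleOperator(tm_inv, alpha=alpha), tol=tol, max_iter=max_iter)
    rv.kind = "cheirank"
    return rv
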