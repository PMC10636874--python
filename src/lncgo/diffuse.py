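"""Random walk with restart on the global network and PPMI re-weighting.

The walker starts at a node and at each step either follows a weighted edge
(probability alpha) or teleports back to its start node (probability
1 - alpha), iterating

    P_k = alpha * P_{k-1} @ A + (1 - alpha) * P_0,     P_0 = I

until the per-row change plateaus ("diffusion state").  Row i of the
converged state is the walker's stationary distribution when started from
node i; it mixes local and global network structure.

Transition probabilities follow A[i, j] = G[i, j] / sum_k G[k, i]: each
entry of the symmetric adjacency matrix is divided by the weighted degree of
the source node, so every row of A (and hence of the diffusion state) sums
to 1.  For a symmetric G that degree is simultaneously the row and the
column sum of node i.

The diffusion state is then re-weighted entrywise into a positive pointwise
mutual information (PPMI) matrix, which damps the influence of high-degree
hub rows/columns before feature learning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .netbuild import GlobalNetwork

_SYMMETRY_TOL = 1e-9


@dataclass
class TransitionMatrix:
    """Row-stochastic step-probability matrix with an isolation mask.

    Isolated (zero-degree) nodes get a unit self-probability so the matrix
    stays stochastic without coupling them to the rest of the graph.
    """

    matrix: np.ndarray
    isolated: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DiffusionConfig:
    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 100
    state_mode: str = "converged"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"restart parameter alpha={self.alpha} outside [0, 1]")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.state_mode not in ("converged", "accumulated"):
            raise ValueError(f"unknown state_mode {self.state_mode!r}")


@dataclass
class DiffusionState:
    """Per-start-node walk probabilities; row i is the state started from i."""

    matrix: np.ndarray
    n_iter: int
    converged: bool
    state_mode: str = "converged"


@dataclass
class PPMIMatrix:
    matrix: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def transition_matrix(G: GlobalNetwork | np.ndarray | sp.spmatrix) -> TransitionMatrix:
    """Degree-normalize a symmetric nonnegative adjacency matrix.

    ``A[i, j] = G[i, j] / sum_k G[k, i]``; rows of isolated nodes become unit
    vectors on the diagonal (the walker stays put).
    """
    if isinstance(G, GlobalNetwork):
        dense = G.toarray()
    elif sp.issparse(G):
        dense = G.toarray()
    else:
        dense = np.asarray(G, dtype=float)
    if dense.ndim != 2 or dense.shape[0] != dense.shape[1]:
        raise ValueError("adjacency matrix must be square")
    if dense.min(initial=0.0) < 0:
        raise ValueError("adjacency matrix must be nonnegative")
    if np.abs(dense - dense.T).max(initial=0.0) > _SYMMETRY_TOL:
        raise ValueError("adjacency matrix must be symmetric")
    deg = dense.sum(axis=0)  # == row sums, by symmetry
    isolated = deg == 0
    safe = np.where(isolated, 1.0, deg)
    A = dense / safe[:, None]
    for i in np.flatnonzero(isolated):
        A[i, i] = 1.0
    return TransitionMatrix(matrix=A, isolated=isolated)


def rwr(A: TransitionMatrix, cfg: DiffusionConfig | None = None) -> DiffusionState:
    """Iterate the restart walk from every node simultaneously.

    Stops when the largest per-row L1 change drops below ``cfg.tol`` or
    after ``cfg.max_iter`` iterations.  In ``accumulated`` mode the sum of
    the per-step matrices P_1 + ... + P_K is returned instead of the final
    P_K (the construction some network-embedding pipelines use); the
    convergence test is always on the P_k sequence itself.
    """
    cfg = cfg or DiffusionConfig()
    n = A.n
    P0 = np.eye(n)
    P = P0.copy()
    acc = np.zeros((n, n))
    converged = False
    k = 0
    for k in range(1, cfg.max_iter + 1):
        P_next = cfg.alpha * (P @ A.matrix) + (1.0 - cfg.alpha) * P0
        delta = np.abs(P_next - P).sum(axis=1).max()
        P = P_next
        acc += P
        if delta < cfg.tol:
            converged = True
            break
    out = acc if cfg.state_mode == "accumulated" else P
    return DiffusionState(matrix=out, n_iter=k, converged=converged,
                          state_mode=cfg.state_mode)


def rwr_closed_form(A: TransitionMatrix, alpha: float) -> np.ndarray:
    """Exact fixed point (1 - alpha) * P_0 * (I - alpha A)^{-1} (alpha < 1)."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("closed form requires 0 <= alpha < 1")
    n = A.n
    return (1.0 - alpha) * np.linalg.inv(np.eye(n) - alpha * A.matrix)


def ppmi(P: DiffusionState | np.ndarray, log_base: float | None = None) -> PPMIMatrix:
    """Positive pointwise mutual information of a nonnegative matrix.

    Treating P (up to scale) as a joint mass over (row, column) pairs with
    marginals r_i and c_j:

        X[i, j] = max(0, log( P[i, j] * total / (r_i * c_j) ))

    Zeros of P map to zeros of X; the result is invariant to multiplying P
    by a positive scalar.  ``log_base`` defaults to the natural log.
    """
    M = P.matrix if isinstance(P, DiffusionState) else np.asarray(P, dtype=float)
    if M.min(initial=0.0) < 0:
        raise ValueError("PPMI input must be nonnegative")
    total = M.sum()
    if total == 0:
        raise ValueError("PPMI undefined for an all-zero matrix")
    r = M.sum(axis=1)
    c = M.sum(axis=0)
    denom = np.outer(r, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        X = np.log(M * total / denom)
    X[~np.isfinite(X)] = 0.0  # zeros of M (and zero marginals) map to 0
    np.maximum(X, 0.0, out=X)
    if log_base is not None:
        X /= math.log(log_base)
    return PPMIMatrix(matrix=X)
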