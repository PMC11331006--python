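"""Similarity network fusion (SNF) over per-view patient similarities.

Each view yields a scaled-exponential affinity kernel
``W_ij = exp(-d^2(x_i, x_j) / (lambda * eps_ij))`` where ``d`` is Euclidean
distance and ``eps_ij`` averages the mean k-nearest-neighbour distances of
``i`` and ``j`` with ``d(x_i, x_j)`` to remove per-view scale. The full
kernel is row-normalized into a transition matrix with its diagonal pinned
to 1/2, and a sparse local kernel keeps only each patient's k strongest
neighbours. Cross-diffusion then repeatedly pushes each view's transition
matrix through the other views' local kernels until the views agree; the
fused network is the view average, projected back onto the symmetric
row-stochastic set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .datatypes import OmicsBlock


@dataclass
class AffinityMatrix:
    W: np.ndarray
    lambda_param: float
    k_neighbors: int


@dataclass
class TransitionMatrix:
    P: np.ndarray


@dataclass
class LocalKernel:
    L: np.ndarray
    neighbor_sets: list[np.ndarray]


@dataclass
class FusedNetwork:
    S: np.ndarray
    patient_ids: np.ndarray
    n_views: int
    n_iterations: int
    convergence_trace: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.patient_ids, columns=self.patient_ids)

    def to_edge_list(self) -> pd.DataFrame:
        ii, jj = np.triu_indices(len(self.S), k=1)
        return pd.DataFrame(
            {
                "id_a": self.patient_ids[ii],
                "id_b": self.patient_ids[jj],
                "weight": self.S[ii, jj],
            }
        )


def default_k(n: int) -> int:
    """Neighbourhood size heuristic: a tenth of the cohort, at least 3."""
    return max(n // 10, 3)


def pairwise_affinity(block: OmicsBlock, lambda_param: float = 0.5, k: int | None = None) -> AffinityMatrix:
    """Scaled-exponential affinity kernel of one view (symmetric, diag 1)."""
    n = block.n_patients
    if k is None:
        k = default_k(n)
    if lambda_param <= 0:
        raise ValueError("lambda_param must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of patients")
    if block.has_missing():
        raise ValueError("affinity requires imputed data")
    dist = squareform(pdist(block.values, metric="euclidean"))
    # mean distance to the k nearest other patients
    sorted_d = np.sort(dist, axis=1)[:, 1 : k + 1]
    mu = sorted_d.mean(axis=1)
    eps = (mu[:, None] + mu[None, :] + dist) / 3.0
    eps = np.maximum(eps, 1e-12)
    W = np.exp(-(dist**2) / (lambda_param * eps))
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return AffinityMatrix(W=W, lambda_param=lambda_param, k_neighbors=k)


def row_normalize(aff: AffinityMatrix | np.ndarray) -> TransitionMatrix:
    """Full-kernel transition matrix: diagonal 1/2, off-diagonal mass 1/2."""
    W = aff.W if isinstance(aff, AffinityMatrix) else np.asarray(aff, dtype=float)
    n = len(W)
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    sums = off.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("isolated patient: a row has no off-diagonal affinity")
    P = off / (2.0 * sums[:, None])
    np.fill_diagonal(P, 0.5)
    return TransitionMatrix(P=P)


def local_kernel(aff: AffinityMatrix, k: int | None = None) -> LocalKernel:
    """Sparse kernel keeping each row's k highest-affinity neighbours.

    Ties in affinity are broken toward the smaller patient index; the
    retained entries are renormalized to sum to 1 per row.
    """
    W = aff.W
    n = len(W)
    if k is None:
        k = aff.k_neighbors
    if k >= n:
        raise ValueError("k must be smaller than the number of patients")
    L = np.zeros_like(W)
    neighbor_sets: list[np.ndarray] = []
    for i in range(n):
        order = [j for j in range(n) if j != i]
        # stable sort on -affinity keeps smaller index first among ties
        order.sort(key=lambda j: -W[i, j])
        nbrs = np.array(sorted(order[:k]))
        neighbor_sets.append(nbrs)
        L[i, nbrs] = W[i, nbrs] / W[i, nbrs].sum()
    return LocalKernel(L=L, neighbor_sets=neighbor_sets)


def _sym_row_stochastic(S: np.ndarray, tol: float = 1e-12, max_iter: int = 1000) -> np.ndarray:
    """Project a positive symmetric matrix onto the doubly-stochastic set.

    Symmetric Sinkhorn scaling: S <- D^-1/2 S D^-1/2 with D the row sums,
    which preserves symmetry and converges for positive matrices; the result
    is symmetric with unit row sums.
    """
    S = (S + S.T) / 2.0
    for _ in range(max_iter):
        r = S.sum(axis=1)
        if np.abs(r - 1.0).max() < tol:
            break
        d = 1.0 / np.sqrt(r)
        S = S * d[:, None] * d[None, :]
    return (S + S.T) / 2.0


def snf_fuse(
    views: list[OmicsBlock],
    lambda_param: float = 0.5,
    k: int | None = None,
    n_iter: int = 20,
) -> FusedNetwork:
    """Cross-diffuse per-view transition matrices into one fused network.

    Each iteration replaces view v's matrix by
    ``L(v) @ mean_of_other_views @ L(v).T`` followed by re-symmetrization
    and row renormalization, keeping each matrix a valid transition kernel.
    The fused output averages the converged views and is then projected to
    be simultaneously symmetric and row-stochastic. ``convergence_trace``
    records the largest per-view Frobenius-norm change at each iteration.
    """
    m = len(views)
    if m < 2:
        raise ValueError("fusion needs at least two views")
    ids = views[0].patient_ids
    for v in views[1:]:
        if not np.array_equal(v.patient_ids, ids):
            raise ValueError("views must share aligned patients")
    n = len(ids)
    if k is None:
        k = default_k(n)

    P_list, L_list = [], []
    for block in views:
        aff = pairwise_affinity(block, lambda_param, k)
        P_list.append(row_normalize(aff).P)
        L_list.append(local_kernel(aff, k).L)

    trace: list[float] = []
    for _ in range(n_iter):
        new_P = []
        delta = 0.0
        for v in range(m):
            others = sum(P_list[u] for u in range(m) if u != v) / (m - 1)
            P = L_list[v] @ others @ L_list[v].T
            # re-symmetrize and renormalize to the half-mass transition form
            # (diagonal pinned to 1/2); a plain row scaling would let the
            # cross-diffusion mix to a structureless stationary matrix
            P = (P + P.T) / 2.0
            P = row_normalize(P).P
            delta = max(delta, float(np.linalg.norm(P - P_list[v])))
            new_P.append(P)
        P_list = new_P
        trace.append(delta)

    S = sum(P_list) / m
    S = _sym_row_stochastic(S)
    return FusedNetwork(
        S=S, patient_ids=ids, n_views=m, n_iterations=n_iter, convergence_trace=trace
    )
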