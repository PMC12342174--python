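"""Similarity network fusion: merge per-omics affinity matrices into one
patient network by iterated cross-diffusion."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FusedNetwork",
    "normalize_similarity",
    "local_affinity",
    "fuse",
]


@dataclass
class FusedNetwork:
    """Per-omics normalized and local-affinity matrices plus the fused
    average after ``iterations`` cross-diffusion updates."""

    P_list: list[np.ndarray]
    S_list: list[np.ndarray]
    P_fused: np.ndarray
    m: int
    iterations: int
    k_neighbors: int
    convergence: list[float] = field(default_factory=list)


def normalize_similarity(A: np.ndarray) -> np.ndarray:
    """Row-stochastic patient similarity with self-similarity fixed at 0.5.

    P(i,i) = 1/2 and P(i,j) = A(i,j) / (2 * sum_{k != i} A(i,k)) for
    j != i, so every row sums to exactly 1.
    """
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("affinity matrix must be non-negative")
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    if (row <= 0).any():
        bad = np.flatnonzero(row <= 0)
        raise ValueError(
            f"rows {bad.tolist()} have zero off-diagonal affinity "
            "(disconnected patients)")
    P = off / (2.0 * row[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def local_affinity(A: np.ndarray, k_neighbors: int) -> np.ndarray:
    """K-nearest-neighbor-restricted row-normalized affinity.

    S(i,j) = A(i,j) / sum_{k in N_i} A(i,k) when j is among i's
    ``k_neighbors`` most similar samples (self excluded), else 0.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= n:
        warnings.warn(
            f"k_neighbors={k_neighbors} >= n={n}; clamping to {n - 1}")
        k_neighbors = n - 1
    off = A.copy()
    np.fill_diagonal(off, -np.inf)
    # indices of the k largest off-diagonal entries per row (stable order)
    nbr = np.argsort(-off, axis=1, kind="stable")[:, :k_neighbors]
    mask = np.zeros_like(A, dtype=bool)
    np.put_along_axis(mask, nbr, True, axis=1)
    S = np.where(mask, A, 0.0)
    denom = S.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0  # all-zero neighborhoods stay all-zero
    return S / denom


def fuse(A_list: list[np.ndarray], k_neighbors: int = 20,
         iterations: int = 20, renormalize: bool = True,
         symmetrize: bool = True, tol: float | None = None) -> FusedNetwork:
    """Cross-diffuse per-omics similarity networks into one fused network.

    Each view's similarity is updated simultaneously as
    ``P_u <- S_u @ mean(P_k for k != u) @ S_u.T`` using the previous
    iteration's matrices, then (by default) symmetrized and renormalized
    to the row-stochastic half-self-similarity form. The fused network is
    the average of the views after the final iteration.

    ``tol`` optionally stops early when the largest absolute change across
    views drops below it. A single view degenerates to plain
    normalization, with a warning.
    """
    if not A_list:
        raise ValueError("no affinity matrices to fuse")
    m = len(A_list)
    shapes = {a.shape for a in A_list}
    if len(shapes) != 1:
        raise ValueError(f"affinity matrices differ in shape: {shapes}")
    if m == 1:
        warnings.warn("only one omics view: fusion degenerates to "
                      "similarity normalization")
        P = normalize_similarity(A_list[0])
        S = local_affinity(A_list[0], k_neighbors)
        return FusedNetwork(P_list=[P], S_list=[S], P_fused=P, m=1,
                            iterations=0, k_neighbors=k_neighbors)

    P_list = [normalize_similarity(A) for A in A_list]
    S_list = [local_affinity(A, k_neighbors) for A in A_list]

    convergence: list[float] = []
    done = 0
    for _ in range(iterations):
        cross = []
        for u in range(m):
            other = sum(P_list[k] for k in range(m) if k != u) / (m - 1)
            cross.append(S_list[u] @ other @ S_list[u].T)
        if symmetrize:
            cross = [(P + P.T) / 2.0 for P in cross]
        if renormalize:
            cross = [normalize_similarity(P) for P in cross]
        delta = max(float(np.max(np.abs(new - old)))
                    for new, old in zip(cross, P_list))
        convergence.append(delta)
        P_list = cross
        done += 1
        if tol is not None and delta < tol:
            break

    P_fused = sum(P_list) / m
    return FusedNetwork(P_list=P_list, S_list=S_list, P_fused=P_fused,
                        m=m, iterations=done, k_neighbors=k_neighbors,
                        convergence=convergence)
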