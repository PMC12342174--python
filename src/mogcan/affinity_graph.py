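"""Patient affinity graphs: scaled exponential kernel, top-percentile
sparsification, row-normalized Laplacian, and dynamic threshold selection.

The kernel exponent convention is configurable. ``paper_literal`` feeds the
squared Euclidean distance to the exponent exactly once and builds the
scaling factor from squared distances; ``snf_original`` builds the scaling
factor from plain Euclidean distances while the exponent still uses the
squared distance (the convention of reference SNF implementations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "AffinityGraph",
    "SingularDegreeError",
    "pairwise_squared_distance",
    "scaling_factor",
    "affinity_kernel",
    "build_affinity",
    "sparsify",
    "degree_and_laplacian",
    "dynamic_threshold_select",
]


class SingularDegreeError(np.linalg.LinAlgError):
    """The degree matrix is singular: some node has zero degree."""


@dataclass
class AffinityGraph:
    """A dense affinity matrix together with its sparsified form and
    row-normalized Laplacian."""

    A: np.ndarray
    mu: float
    k_neighbors: int
    A_sparse: np.ndarray | None = None
    threshold_value: float | None = None
    retained_fraction: float | None = None
    L: np.ndarray | None = None
    D: np.ndarray | None = None
    name: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Weighted (i, j, w) triples of the sparsified matrix, i < j."""
        if self.A_sparse is None:
            raise ValueError("graph has not been sparsified")
        iu, ju = np.nonzero(np.triu(self.A_sparse, k=1))
        return [(int(i), int(j), float(self.A_sparse[i, j]))
                for i, j in zip(iu, ju)]


def pairwise_squared_distance(values: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance between every pair of rows.

    rho(i, j) = sum_m (x_im - x_jm)^2; symmetric with a zero diagonal.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("input contains missing values; clean it first")
    rho = squareform(pdist(values, metric="sqeuclidean"))
    return rho


def scaling_factor(rho: np.ndarray, k_neighbors: int = 20) -> np.ndarray:
    """Average-local-distance scaling term for the exponential kernel.

    nu(i, j) = (mean_k(rho(i, .)) + mean_k(rho(j, .)) + rho(i, j)) / 3
    where mean_k averages each sample's distances to its k nearest
    neighbors (self excluded). ``k_neighbors >= n`` is clamped to n-1
    with a warning.
    """
    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= n:
        warnings.warn(
            f"k_neighbors={k_neighbors} >= n={n}; clamping to {n - 1}")
        k_neighbors = n - 1
    # k smallest off-diagonal distances per row
    off = rho.copy()
    np.fill_diagonal(off, np.inf)
    part = np.partition(off, k_neighbors - 1, axis=1)[:, :k_neighbors]
    local_mean = part.mean(axis=1)
    return (local_mean[:, None] + local_mean[None, :] + rho) / 3.0


def affinity_kernel(rho: np.ndarray, nu: np.ndarray,
                    mu: float = 0.5) -> np.ndarray:
    """Scaled exponential similarity kernel A = exp(-rho / (mu * nu)).

    ``rho`` is the quantity entering the exponent (squared distances under
    the default convention). The diagonal is set to 1; zero off-diagonal
    scaling (exact duplicate samples) maps to kernel value 1.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    rho = np.asarray(rho, dtype=float)
    nu = np.asarray(nu, dtype=float)
    denom = mu * nu
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.exp(-np.where(denom > 0, rho / np.where(denom > 0, denom, 1.0),
                             0.0))
    A[denom <= 0] = 1.0  # duplicate pairs: rho == 0, treat as identical
    np.fill_diagonal(A, 1.0)
    return (A + A.T) / 2.0


def build_affinity(values: np.ndarray, k_neighbors: int = 20,
                   mu: float = 0.5,
                   kernel_distance_convention: str = "paper_literal",
                   name: str = "") -> AffinityGraph:
    """Build the dense affinity matrix for one omics view."""
    rho_sq = pairwise_squared_distance(values)
    if kernel_distance_convention == "paper_literal":
        nu = scaling_factor(rho_sq, k_neighbors)
    elif kernel_distance_convention == "snf_original":
        nu = scaling_factor(np.sqrt(rho_sq), k_neighbors)
    else:
        raise ValueError(
            "kernel_distance_convention must be 'paper_literal' or "
            "'snf_original'")
    A = affinity_kernel(rho_sq, nu, mu)
    return AffinityGraph(A=A, mu=mu, k_neighbors=k_neighbors, name=name,
                         meta={"convention": kernel_distance_convention})


def sparsify(A: np.ndarray, retained_fraction: float
             ) -> tuple[np.ndarray, float, int]:
    """Keep the top ``retained_fraction`` of entries of ``A``, zero the rest.

    The threshold is the floor(p * n^2)-th largest entry (all n^2 cells
    ranked, diagonal and both symmetric copies included); entries >= the
    threshold keep their value, so ties at the threshold may inflate the
    retained count. The result is symmetrized by keeping an entry when
    either symmetric copy survives.

    Returns ``(A_sparse, threshold, primary_count)`` where ``primary_count``
    is the number of entries >= threshold before tie inflation or
    symmetrization (exactly floor(p * n^2) when all entries are distinct).
    """
    if retained_fraction <= 0:
        raise ValueError("retained_fraction must be in (0, 1]")
    if retained_fraction > 1:
        raise ValueError("retained_fraction must be in (0, 1]")
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    m = int(np.floor(retained_fraction * n * n))
    m = max(1, min(m, n * n))
    flat = np.sort(A, axis=None)[::-1]
    eps = float(flat[m - 1])
    keep = A >= eps
    primary_count = int(keep.sum())
    keep = keep | keep.T  # undirected graph: either copy survives
    A_sparse = np.where(keep, A, 0.0)
    return A_sparse, eps, primary_count


def degree_and_laplacian(A_sparse: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal degree matrix D and row-normalized Laplacian L = D^-1 A.

    Raises :class:`SingularDegreeError` when a node has zero degree.
    """
    A_sparse = np.asarray(A_sparse, dtype=float)
    if (A_sparse < 0).any():
        raise ValueError("affinity matrix must be non-negative")
    deg = A_sparse.sum(axis=1)
    if (deg == 0).any():
        bad = np.flatnonzero(deg == 0)
        raise SingularDegreeError(
            f"degree matrix is singular: zero-degree nodes {bad.tolist()}")
    D = np.diag(deg)
    L = A_sparse / deg[:, None]
    return D, L


def _full_rank_degrees(A_sparse: np.ndarray) -> bool:
    """Exact full-rank check for the diagonal degree matrix: every node
    retains at least one incident non-zero entry (zero-pattern only, so it
    is identical for the weighted and binarized sparsifications)."""
    return bool((np.count_nonzero(A_sparse, axis=1) > 0).all())


def dynamic_threshold_select(A: np.ndarray, p0: float = 0.01,
                             step: float = 0.005
                             ) -> tuple[float, np.ndarray, np.ndarray]:
    """Smallest grid retention fraction whose degree matrix is full rank.

    Scans p in {p0, p0+step, ...} (clipped at 1.0), sparsifies at each p,
    and returns the first p whose sparsified matrix leaves no node
    isolated, together with that sparse matrix and its Laplacian.
    """
    if p0 <= 0 or step <= 0:
        raise ValueError("p0 and step must be positive")
    p = p0
    while True:
        p_eff = min(p, 1.0)
        A_sparse, eps, _ = sparsify(A, p_eff)
        if _full_rank_degrees(A_sparse):
            _, L = degree_and_laplacian(A_sparse)
            return p_eff, A_sparse, L
        if p_eff >= 1.0:
            raise SingularDegreeError(
                "no retention fraction up to 1.0 yields a full-rank degree "
                "matrix (the affinity matrix has an all-zero row)")
        p += step


def sparsify_graph(graph: AffinityGraph, p0: float = 0.01,
                   step: float = 0.005) -> AffinityGraph:
    """Run dynamic threshold selection and fill the graph's sparse fields."""
    p_star, A_sparse, L = dynamic_threshold_select(graph.A, p0, step)
    _, eps, _ = sparsify(graph.A, p_star)
    graph.A_sparse = A_sparse
    graph.threshold_value = eps
    graph.retained_fraction = p_star
    graph.D = np.diag(A_sparse.sum(axis=1))
    graph.L = L
    return graph
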