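"""Unsupervised local-scale spectral clustering.

Pipeline: per-point local scales (distance to the T-th nearest neighbour),
Gaussian affinity ``W_ij = exp(-d^2(x_i, x_j) / (sigma_i * sigma_j))``,
normalized graph Laplacian ``L = I - D^{-1/2} W D^{-1/2}``, embedding by the
K smallest-eigenvalue eigenvectors with row normalization, and k-means on
the embedded rows.  The local scale adapts the affinity bandwidth to local
density, so clusters of very different volume are treated even-handedly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "AffinityGraph",
    "SpectralEmbedding",
    "Partition",
    "local_scales",
    "base_affinity",
    "normalized_laplacian",
    "spectral_embed",
    "kmeans_partition",
    "cluster_unsupervised",
]

SCALE_FLOOR = 1e-12
DEFAULT_T = 7  # neighbour index recommended by the local-scaling literature
DENSE_EIG_LIMIT = 2000
KMEANS_RESTARTS = 20


@dataclass
class AffinityGraph:
    """Symmetric non-negative weight matrix with degrees and Laplacian."""

    W: np.ndarray
    degrees: np.ndarray | None = None
    laplacian: np.ndarray | None = None


@dataclass
class SpectralEmbedding:
    """Row-normalized spectral coordinates Y and the raw eigenvectors U."""

    Y: np.ndarray
    U: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class Partition:
    """Cluster label per sample, labels in 1..K."""

    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        attained = np.unique(self.labels)
        if attained.min() < 1 or attained.max() > self.K:
            raise ValueError(f"labels must lie in 1..{self.K}")
        if len(attained) < self.K:
            logger.warning("partition attains %d of %d clusters", len(attained), self.K)


def local_scales(X: np.ndarray, T: int = DEFAULT_T) -> np.ndarray:
    """sigma_i = Euclidean distance from x_i to its T-th nearest other point."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= T <= n - 1:
        raise ValueError(f"T={T} must be in [1, n-1={n - 1}]")
    D = squareform(pdist(X))
    # column 0 after sorting is the point itself (distance 0)
    sigma = np.sort(D, axis=1)[:, T]
    floored = sigma < SCALE_FLOOR
    if floored.any():
        logger.warning("floored %d local scale(s) at %g", int(floored.sum()), SCALE_FLOOR)
        sigma[floored] = SCALE_FLOOR
    return sigma


def base_affinity(X: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """W_ij = exp(-d^2(x_i, x_j) / (sigma_i sigma_j)), zero diagonal."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite coordinates")
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any():
        raise ValueError("local scales must be strictly positive")
    D2 = squareform(pdist(X, "sqeuclidean"))
    W = np.exp(-D2 / np.outer(sigma, sigma))
    np.fill_diagonal(W, 0.0)
    return W


def normalized_laplacian(W: np.ndarray) -> AffinityGraph:
    """L = I - D^{-1/2} W D^{-1/2}; isolated vertices get D^{-1/2} entry 0."""
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T):
        raise ValueError("affinity matrix must be symmetric")
    if (W < 0).any():
        raise ValueError("affinity matrix must be non-negative")
    degrees = W.sum(axis=1)
    isolated = degrees == 0
    if isolated.any():
        logger.warning("%d isolated vertex/vertices in affinity graph", int(isolated.sum()))
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(isolated, 0.0, 1.0 / np.sqrt(np.where(isolated, 1.0, degrees)))
    L = -W * np.outer(d_inv_sqrt, d_inv_sqrt)
    np.fill_diagonal(L, 1.0)
    L = (L + L.T) / 2.0  # guard symmetry against round-off
    return AffinityGraph(W=W, degrees=degrees, laplacian=L)


def spectral_embed(graph: AffinityGraph | np.ndarray, K: int) -> SpectralEmbedding:
    """Embed via the K smallest-eigenvalue eigenvectors of L, rows normalized."""
    L = graph.laplacian if isinstance(graph, AffinityGraph) else np.asarray(graph, dtype=float)
    n = L.shape[0]
    if not 1 <= K <= n:
        raise ValueError(f"K={K} must be in [1, n={n}]")
    if n <= DENSE_EIG_LIMIT:
        eigvals, eigvecs = np.linalg.eigh(L)
        lam, U = eigvals[:K], eigvecs[:, :K]
    else:
        from scipy.sparse.linalg import eigsh

        try:
            lam, U = eigsh(L, k=K, sigma=-1e-6, which="LM")
        except Exception as e:  # pragma: no cover - solver fallback
            raise np.linalg.LinAlgError(f"iterative eigensolver failed: {e}") from e
        order = np.argsort(lam)
        lam, U = lam[order], U[:, order]
    # deterministic orientation across backends
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    norms = np.linalg.norm(U, axis=1)
    zero = norms == 0
    Y = U.copy()
    if zero.any():
        logger.warning("%d zero embedding row(s) mapped to e_1", int(zero.sum()))
        Y[zero, 0] = 1.0
        norms[zero] = 1.0
    Y = Y / norms[:, None]
    return SpectralEmbedding(Y=Y, U=U, eigenvalues=lam)


def kmeans_partition(Y: np.ndarray, K: int, seed: int) -> Partition:
    """k-means++ with multiple seeded restarts; labels returned in 1..K."""
    km = KMeans(n_clusters=K, n_init=KMEANS_RESTARTS, random_state=seed)
    labels = km.fit_predict(Y) + 1
    return Partition(labels=labels, K=K)


def cluster_unsupervised(
    X: np.ndarray, K: int, T: int = DEFAULT_T, seed: int = 0
) -> Partition:
    """Full local-scale spectral clustering of coordinate rows into K clusters."""
    X = np.asarray(X, dtype=float)
    if K == 1:
        return Partition(labels=np.ones(X.shape[0], dtype=int), K=1)
    sigma = local_scales(X, T)
    W = base_affinity(X, sigma)
    graph = normalized_laplacian(W)
    emb = spectral_embed(graph, K)
    return kmeans_partition(emb.Y, K, seed)
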