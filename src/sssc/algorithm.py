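"""Semi-supervised spectral clustering (SSSC) with constraint-adjusted affinities.

The affinity matrix from the local-scale pipeline is modified with must-link
and cannot-link information in four sub-steps:

  2.a  base Gaussian affinity with local scales;
  2.b  every must-link entry is set to 1, every cannot-link entry to 0;
  2.c  each unconstrained sample ``k`` (no cannot-link) finds its most
       similar cannot-linked anchor ``c_k``; affinities between ``k`` and
       every sample cannot-linked to ``c_k`` are divided by ``beta >= 1`` —
       a point drawn toward one side of a cannot-link pair is pushed away
       from the other side;
  2.d  (only if ``alpha = 1``) each sample ``k`` with no must-link finds its
       most similar must-linked anchor ``m_k``; affinities between ``k`` and
       every sample must-linked to ``m_k`` are set to ``W[m_k, k]``, so the
       whole must-link clique looks equally similar to ``k``.

With ``alpha = 0`` and ``beta = 1`` only step 2.b has any effect and the
procedure reduces to the classic similarity-overwriting semi-supervised
spectral clustering baseline; with an empty constraint set it reduces to the
unsupervised pipeline exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constraints import ConstraintSet
from .spectral import (
    DEFAULT_T,
    Partition,
    base_affinity,
    kmeans_partition,
    local_scales,
    normalized_laplacian,
    spectral_embed,
)

__all__ = ["SSSCParams", "adjust_affinity", "cluster_sssc"]


@dataclass
class SSSCParams:
    """Tuning parameters of the semi-supervised spectral clustering run.

    K: number of clusters; alpha in {0, 1} switches the must-link anchor
    step 2.d; beta >= 1 divides affinities leaking across cannot-links in
    step 2.c; T is the local-scale neighbour index; seed drives k-means.
    """

    K: int
    alpha: int = 0
    beta: float = 1.0
    T: int = DEFAULT_T
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha not in (0, 1):
            raise ValueError(f"alpha={self.alpha} must be 0 or 1")
        if self.beta < 1:
            raise ValueError(f"beta={self.beta} must be >= 1")
        if self.K < 1:
            raise ValueError(f"K={self.K} must be >= 1")
        if self.T < 1:
            raise ValueError(f"T={self.T} must be >= 1")


def adjust_affinity(
    W: np.ndarray, c: ConstraintSet, alpha: int = 0, beta: float = 1.0
) -> np.ndarray:
    """Apply constraint steps 2.b-2.d to a base affinity matrix.

    Requires a sanitized (contradiction-free) constraint set.  The anchor
    argmaxes of steps 2.c and 2.d are both taken on the matrix state after
    step 2.b; ties are broken toward the lowest sample index.  Entries stay
    in [0, 1] and the matrix stays symmetric with zero diagonal.
    """
    if beta < 1:
        raise ValueError(f"beta={beta} must be >= 1")
    if alpha not in (0, 1):
        raise ValueError(f"alpha={alpha} must be 0 or 1")
    if not c.is_contradiction_free():
        raise ValueError("constraint set has contradictions; sanitize it first")
    W = np.array(W, dtype=float)
    n = W.shape[0]
    if c.n != n:
        raise ValueError("constraint set size does not match affinity matrix")

    # step 2.b: overwrite constrained pairs
    must, cannot = c.must.astype(bool), c.cannot.astype(bool)
    W[must] = 1.0
    W[cannot] = 0.0

    W_after_b = W.copy()  # anchor argmaxes read this snapshot
    v_cannot = c.constrained_cannot()
    v_must = c.constrained_must()

    # step 2.c: penalize leakage across cannot-links
    if len(v_cannot):
        in_cannot = np.zeros(n, dtype=bool)
        in_cannot[v_cannot] = True
        for k in np.flatnonzero(~in_cannot):
            c_k = v_cannot[np.argmax(W_after_b[k, v_cannot])]
            targets = np.flatnonzero(cannot[c_k])
            W[targets, k] /= beta
            W[k, targets] = W[targets, k]

    # step 2.d: equalize similarity to whole must-link cliques
    if alpha == 1 and len(v_must):
        in_must = np.zeros(n, dtype=bool)
        in_must[v_must] = True
        for k in np.flatnonzero(~in_must):
            m_k = v_must[np.argmax(W_after_b[k, v_must])]
            anchor_value = W[m_k, k]  # read before overwriting k's column
            targets = np.flatnonzero(must[m_k])
            W[targets, k] = anchor_value
            W[k, targets] = anchor_value

    np.fill_diagonal(W, 0.0)
    return W


def cluster_sssc(X: np.ndarray, c: ConstraintSet, params: SSSCParams) -> Partition:
    """Run the full semi-supervised spectral clustering pipeline.

    local scales -> base affinity -> constraint adjustment -> normalized
    Laplacian -> spectral embedding -> row normalization -> k-means.
    """
    X = np.asarray(X, dtype=float)
    if params.K == 1:
        return Partition(labels=np.ones(X.shape[0], dtype=int), K=1)
    sigma = local_scales(X, params.T)
    W = base_affinity(X, sigma)
    W = adjust_affinity(W, c, alpha=params.alpha, beta=params.beta)
    graph = normalized_laplacian(W)
    emb = spectral_embed(graph, params.K)
    return kmeans_partition(emb.Y, params.K, params.seed)
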