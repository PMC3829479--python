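"""Dimension reduction by eigendecomposition of the sample Gram matrix.

The centered genotype matrix ``Z_c`` (n samples x p variants) is reduced to
per-individual coordinates through the n x n Gram matrix ``H = Z_c @ Z_c.T``:
the coordinates of individual ``i`` are the re-scaled eigenvector entries
``sqrt(lambda_j) * u_j(i)`` for the ``J`` largest eigenvalues.  With the
square-root scaling the rows of the score matrix preserve all pairwise
Euclidean distances of the rows of ``Z_c`` (Gram isometry); an alternative
``lambda_j`` scaling is available via ``scaling="eigenvalue"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCCoordinates", "gram_matrix", "pca_coordinates", "write_scores", "read_scores"]

_EIG_TOL = 1e-9


@dataclass
class PCCoordinates:
    """Principal-component scores with the eigenvalues that produced them."""

    scores: np.ndarray  # (n, J)
    eigenvalues: np.ndarray  # (J,) non-increasing, >= 0
    sample_ids: list[str] | None = None

    @property
    def J(self) -> int:
        return self.scores.shape[1]

    def top(self, J: int) -> np.ndarray:
        """Coordinate matrix restricted to the first ``J`` components."""
        if not 1 <= J <= self.J:
            raise ValueError(f"J={J} outside [1, {self.J}]")
        return self.scores[:, :J]


def gram_matrix(Z_c: np.ndarray, block: int = 4096) -> np.ndarray:
    """``H = Z_c @ Z_c.T`` accumulated over variant blocks.

    Blocking keeps peak memory at O(n^2 + n*block) when Z_c is a memory-mapped
    or otherwise column-sliceable array with very large p.
    """
    Z_c = np.asarray(Z_c, dtype=float)
    n, p = Z_c.shape
    H = np.zeros((n, n))
    for start in range(0, p, block):
        B = Z_c[:, start : start + block]
        H += B @ B.T
    return H


def _fix_signs(U: np.ndarray) -> np.ndarray:
    # make the largest-magnitude entry of each eigenvector positive
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def pca_coordinates(
    Z_c: np.ndarray,
    J: int,
    scaling: str = "sqrt",
    sample_ids: list[str] | None = None,
) -> PCCoordinates:
    """Eigendecompose the Gram matrix and return re-scaled eigenvector scores.

    Parameters
    ----------
    Z_c
        Column-centered matrix, shape ``(n, p)``.
    J
        Number of components to retain, ``1 <= J <= n``.
    scaling
        ``"sqrt"`` (default) scores are ``sqrt(lambda_j) * u_j``;
        ``"eigenvalue"`` scores are ``lambda_j * u_j``.
    """
    Z_c = np.asarray(Z_c, dtype=float)
    if not np.isfinite(Z_c).all():
        raise ValueError("non-finite entries in centered matrix")
    n = Z_c.shape[0]
    if not 1 <= J <= n:
        raise ValueError(f"J={J} must be in [1, n={n}]")
    if scaling not in ("sqrt", "eigenvalue"):
        raise ValueError(f"unknown scaling {scaling!r}")

    H = gram_matrix(Z_c)
    eigvals, eigvecs = np.linalg.eigh(H)  # ascending
    order = np.argsort(eigvals)[::-1][:J]
    lam = eigvals[order]
    U = _fix_signs(eigvecs[:, order])
    # H is a Gram matrix: tiny negative eigenvalues are round-off
    floor = -_EIG_TOL * max(1.0, abs(float(lam[0])))
    if (lam < floor).any():
        raise np.linalg.LinAlgError("Gram matrix produced significantly negative eigenvalues")
    lam = np.clip(lam, 0.0, None)
    factor = np.sqrt(lam) if scaling == "sqrt" else lam
    return PCCoordinates(scores=U * factor, eigenvalues=lam, sample_ids=sample_ids)


def write_scores(pc: PCCoordinates, path, eigenvalue_path=None) -> None:
    """Write scores as TSV (sample_id, PC1..PCJ); eigenvalues as a sidecar TSV."""
    ids = pc.sample_ids or [f"S{i}" for i in range(pc.scores.shape[0])]
    df = pd.DataFrame(pc.scores, index=ids, columns=[f"PC{j + 1}" for j in range(pc.J)])
    df.to_csv(path, sep="\t", index_label="sample_id")
    if eigenvalue_path is not None:
        pd.DataFrame(
            {"component": [f"PC{j + 1}" for j in range(pc.J)], "eigenvalue": pc.eigenvalues}
        ).to_csv(eigenvalue_path, sep="\t", index=False)


def read_scores(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(s) for s in df.index]
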