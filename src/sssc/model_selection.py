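"""Cross-validated prediction-strength selection of the tuning parameters.

The data are randomly split in half; each half is clustered independently
with SSSC at a candidate parameter point theta = (K, alpha, beta, T)
(constraints restricted to the half's own samples); the training labels are
transferred to the test half by single-linkage nearest-cluster assignment,
and the adjusted Rand index between the transferred labels and the test
half's own clustering is the *prediction strength* of theta for that split.
Averaging over repeated splits and maximizing picks theta-hat; treating the
number of retained principal components J as one more parameter and
maximizing the per-J best mean strength picks J-hat.

One master seed spawns an independent RNG stream per repeat that is shared
across grid points, so every theta is scored on identical splits (a paired
comparison, lowering selection variance).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .algorithm import SSSCParams, cluster_sssc
from .constraints import ConstraintSet
from .metrics import adjusted_rand_index
from .spectral import DEFAULT_T

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterGrid",
    "SelectionResult",
    "split_half",
    "transfer_labels",
    "prediction_strength_once",
    "select_parameters",
]


@dataclass
class ParameterGrid:
    """Candidate values for (K, alpha, beta, T) and the PC count J."""

    Ks: list[int]
    alphas: list[int] = field(default_factory=lambda: [0])
    betas: list[float] = field(default_factory=lambda: [1.0])
    Ts: list[int] = field(default_factory=lambda: [DEFAULT_T])
    Js: list[int] | None = None
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name, vals in (("Ks", self.Ks), ("alphas", self.alphas),
                           ("betas", self.betas), ("Ts", self.Ts)):
            if not vals:
                raise ValueError(f"{name} must be nonempty")
        if any(a not in (0, 1) for a in self.alphas):
            raise ValueError("alphas must be a subset of {0, 1}")
        if any(b < 1 for b in self.betas):
            raise ValueError("betas must all be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def thetas(self):
        return itertools.product(self.Ks, self.alphas, self.betas, self.Ts)


@dataclass
class SelectionResult:
    best_theta: tuple[int, int, float, int]
    best_J: int
    best_strength: float
    strength_table: pd.DataFrame  # one row per (J, K, alpha, beta, T, repeat)

    def mean_table(self) -> pd.DataFrame:
        return (
            self.strength_table.groupby(["J", "K", "alpha", "beta", "T"], as_index=False)[
                "strength"
            ].mean()
        )


def split_half(n: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint covering split into sizes ceil(n/2), floor(n/2)."""
    if n < 4:
        raise ValueError(f"n={n} too small for a half split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = (n + 1) // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def transfer_labels(X_te: np.ndarray, X_tr: np.ndarray, l_tr: np.ndarray) -> np.ndarray:
    """Assign each test sample to the nearest training cluster.

    Cluster-to-sample distance is single linkage: the minimum Euclidean
    distance from the sample to any member of the cluster.  Ties go to the
    lowest cluster label.
    """
    l_tr = np.asarray(l_tr)
    D = cdist(np.atleast_2d(X_te), np.atleast_2d(X_tr))
    clusters = np.unique(l_tr)  # sorted: argmin tie -> lowest label
    min_dists = np.column_stack([D[:, l_tr == k].min(axis=1) for k in clusters])
    return clusters[np.argmin(min_dists, axis=1)]


def prediction_strength_once(
    X: np.ndarray,
    c: ConstraintSet,
    theta: tuple[int, int, float, int],
    seed,
) -> float | None:
    """One split-half prediction strength of theta = (K, alpha, beta, T).

    Returns None (logged) when either half is too small to cluster into K
    groups with neighbour index T.
    """
    K, alpha, beta, T = theta
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    tr, te = split_half(X.shape[0], rng)
    if min(len(tr), len(te)) < max(K, T + 1):
        logger.warning("half too small for K=%d, T=%d; strength missing", K, T)
        return None
    km_seed = int(rng.integers(2**31))
    params_tr = SSSCParams(K=K, alpha=alpha, beta=beta, T=T, seed=km_seed)
    params_te = SSSCParams(K=K, alpha=alpha, beta=beta, T=T, seed=km_seed)
    l_tr = cluster_sssc(X[tr], c.restrict(tr), params_tr).labels
    l_te = cluster_sssc(X[te], c.restrict(te), params_te).labels
    l_te_given_tr = transfer_labels(X[te], X[tr], l_tr)
    return adjusted_rand_index(l_te_given_tr, l_te)


def select_parameters(
    scores: np.ndarray,
    c: ConstraintSet,
    grid: ParameterGrid,
) -> SelectionResult:
    """Grid search over (J, K, alpha, beta, T) by mean prediction strength.

    ``scores`` holds principal-component coordinates with enough columns for
    the largest J in the grid; for each candidate J the top-J columns are
    used.  Deterministic given ``grid.seed``.
    """
    scores = np.asarray(scores, dtype=float)
    Js = grid.Js or [scores.shape[1]]
    if max(Js) > scores.shape[1]:
        raise ValueError(f"max J={max(Js)} exceeds available components {scores.shape[1]}")
    repeat_seeds = np.random.SeedSequence(grid.seed).spawn(grid.n_repeats)

    rows = []
    for J in Js:
        X = scores[:, :J]
        for theta in grid.thetas():
            for r, ss in enumerate(repeat_seeds):
                s = prediction_strength_once(X, c, theta, ss)
                rows.append(
                    {"J": J, "K": theta[0], "alpha": theta[1], "beta": theta[2],
                     "T": theta[3], "repeat": r, "strength": s}
                )
    table = pd.DataFrame(rows)
    if table["strength"].isna().all():
        raise ValueError("every grid point was infeasible on every split")
    means = (
        table.dropna(subset=["strength"])
        .groupby(["J", "K", "alpha", "beta", "T"], as_index=False)["strength"]
        .mean()
    )
    dropped = len(list(grid.thetas())) * len(Js) - len(means)
    if dropped:
        logger.warning("%d grid point(s) had no feasible split and were excluded", dropped)
    best = means.loc[means["strength"].idxmax()]
    return SelectionResult(
        best_theta=(int(best["K"]), int(best["alpha"]), float(best["beta"]), int(best["T"])),
        best_J=int(best["J"]),
        best_strength=float(best["strength"]),
        strength_table=table,
    )
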