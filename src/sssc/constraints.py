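"""Must-link / cannot-link constraint matrices.

A :class:`ConstraintSet` holds two symmetric binary n x n matrices: ``must``
(pairs known to share a cluster) and ``cannot`` (pairs known to differ).
Constraints can be derived from partial population labels — a fraction SSR of
individuals per subgroup reveals its label, and every revealed pair becomes a
must-link (same label) or cannot-link (different labels) — or supplied as an
explicit pair list.

Before clustering, constraints are propagated and sanitized:

1. must-links are closed under transitivity,
2. cannot-links are lifted through must-link components
   (``must[i,k] and cannot[k,j]  =>  cannot[i,j]``),
3. any pair carrying both a must-link and a cannot-link after propagation has
   both entries zeroed (contradictory evidence is discarded rather than
   trusted either way).

Rules 1-2 are run jointly to a fixpoint via union-find over must-link
components, so the result does not depend on the order constraints were
listed in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConstraintSet",
    "SemiSupervisedSample",
    "sample_labeled_subset",
    "constraints_from_labels",
    "propagate_and_sanitize",
    "read_constraint_pairs",
    "read_partial_labels",
]


@dataclass
class ConstraintSet:
    """Symmetric binary must-link and cannot-link matrices over n samples."""

    must: np.ndarray
    cannot: np.ndarray

    def __post_init__(self) -> None:
        self.must = np.asarray(self.must, dtype=np.int8)
        self.cannot = np.asarray(self.cannot, dtype=np.int8)
        for name, m in (("must", self.must), ("cannot", self.cannot)):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} matrix must be square")
            if not np.array_equal(m, m.T):
                raise ValueError(f"{name} matrix must be symmetric")
            if np.diag(m).any():
                raise ValueError(f"{name} matrix must have zero diagonal")
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} matrix must be binary")
        if self.must.shape != self.cannot.shape:
            raise ValueError("must and cannot matrices must have equal shape")

    @property
    def n(self) -> int:
        return self.must.shape[0]

    @classmethod
    def empty(cls, n: int) -> "ConstraintSet":
        z = np.zeros((n, n), dtype=np.int8)
        return cls(must=z, cannot=z.copy())

    def is_empty(self) -> bool:
        return not (self.must.any() or self.cannot.any())

    def is_contradiction_free(self) -> bool:
        return not (self.must & self.cannot).any()

    def merge(self, other: "ConstraintSet") -> "ConstraintSet":
        """Logical OR of two constraint sets over the same samples."""
        if other.n != self.n:
            raise ValueError("constraint sets cover different sample counts")
        return ConstraintSet(must=self.must | other.must, cannot=self.cannot | other.cannot)

    def restrict(self, indices: np.ndarray) -> "ConstraintSet":
        """Submatrices over ``indices`` (e.g. a cross-validation half)."""
        idx = np.asarray(indices)
        return ConstraintSet(
            must=self.must[np.ix_(idx, idx)], cannot=self.cannot[np.ix_(idx, idx)]
        )

    def constrained_cannot(self) -> np.ndarray:
        """V_cannot: indices touched by at least one cannot-link."""
        return np.flatnonzero(self.cannot.any(axis=1))

    def constrained_must(self) -> np.ndarray:
        """V_must: indices touched by at least one must-link."""
        return np.flatnonzero(self.must.any(axis=1))


@dataclass
class SemiSupervisedSample:
    """A revealed subset of samples with their known subgroup labels."""

    indices: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices)
        self.labels = np.asarray(self.labels)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("indices must be unique")
        if len(self.indices) != len(self.labels):
            raise ValueError("indices and labels must have equal length")


def sample_labeled_subset(labels, ssr: float, seed: int) -> SemiSupervisedSample:
    """Reveal a fraction ``ssr`` of samples from each subgroup.

    Per subgroup ``g`` with ``n_g`` members, ``round(ssr * n_g)`` members are
    drawn uniformly without replacement; the draw is deterministic given
    ``seed``.
    """
    if not 0 < ssr <= 1:
        raise ValueError(f"ssr={ssr} must be in (0, 1]")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for g in np.unique(labels):
        members = np.flatnonzero(labels == g)
        k = int(round(ssr * len(members)))
        chosen.append(rng.choice(members, size=k, replace=False))
    idx = np.sort(np.concatenate(chosen)).astype(np.intp)
    return SemiSupervisedSample(indices=idx, labels=labels[idx])


def constraints_from_labels(sample: SemiSupervisedSample, n: int) -> ConstraintSet:
    """Pairwise constraints implied by a revealed labeled subset.

    For revealed ``i != j``: must-link iff equal labels, cannot-link iff
    different labels; pairs involving an unrevealed sample stay unconstrained.
    """
    must = np.zeros((n, n), dtype=np.int8)
    cannot = np.zeros((n, n), dtype=np.int8)
    idx = np.asarray(sample.indices)
    lab = np.asarray(sample.labels)
    if len(idx):
        same = (lab[:, None] == lab[None, :]).astype(np.int8)
        np.fill_diagonal(same, 0)
        diff = (lab[:, None] != lab[None, :]).astype(np.int8)
        must[np.ix_(idx, idx)] = same
        cannot[np.ix_(idx, idx)] = diff
    return ConstraintSet(must=must, cannot=cannot)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def propagate_and_sanitize(c: ConstraintSet) -> ConstraintSet:
    """Close constraints under propagation, then remove contradictions.

    Must-links become a union of cliques (transitive closure); cannot-links
    are lifted to whole must-link component pairs; pairs that end up both
    must- and cannot-linked are zeroed in both matrices (with a warning).
    Idempotent and total.
    """
    n = c.n
    uf = _UnionFind(n)
    for i, j in zip(*np.nonzero(np.triu(c.must, 1))):
        uf.union(int(i), int(j))
    comp = np.array([uf.find(i) for i in range(n)])

    # must-links: cliques within each multi-member component
    must = (comp[:, None] == comp[None, :]).astype(np.int8)
    sizes = np.bincount(comp, minlength=n)
    singleton = sizes[comp] == 1
    must[singleton, :] = 0
    must[:, singleton] = 0
    np.fill_diagonal(must, 0)

    # cannot-links lifted to component level: comp pair (a, b) is cannot-linked
    # if any member pair is
    cannot = np.zeros((n, n), dtype=np.int8)
    ci, cj = np.nonzero(c.cannot)
    if len(ci):
        linked = set(zip(comp[ci], comp[cj]))
        comp_pairs = np.zeros((n, n), dtype=np.int8)
        for a, b in linked:
            comp_pairs[a, b] = comp_pairs[b, a] = 1
        cannot = comp_pairs[np.ix_(comp, comp)]
        np.fill_diagonal(cannot, 0)

    contradictions = must & cannot
    if contradictions.any():
        pairs = [(int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(contradictions, 1)))]
        logger.warning(
            "removed %d contradictory constraint pair(s): %s", len(pairs), pairs
        )
        must &= ~contradictions
        cannot &= ~contradictions
    return ConstraintSet(must=must, cannot=cannot)


def read_constraint_pairs(path, sample_ids: list[str]) -> ConstraintSet:
    """Read an explicit pair list: columns sample_id_1, sample_id_2, type."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#",
                     names=["a", "b", "type"], dtype=str, skipinitialspace=True)
    pos = {s: i for i, s in enumerate(sample_ids)}
    n = len(sample_ids)
    c = ConstraintSet.empty(n)
    for _, row in df.iterrows():
        kind = row["type"].strip().lower()
        if kind not in ("must", "cannot"):
            raise ValueError(f"{path}: unknown constraint type {row['type']!r}")
        try:
            i, j = pos[row["a"].strip()], pos[row["b"].strip()]
        except KeyError as e:
            raise ValueError(f"{path}: unknown sample id {e.args[0]!r}") from None
        if i == j:
            raise ValueError(f"{path}: self-constraint on {row['a']!r}")
        target = c.must if kind == "must" else c.cannot
        target[i, j] = target[j, i] = 1
    return c


def read_partial_labels(path, sample_ids: list[str]) -> SemiSupervisedSample:
    """Read a partial-label file: columns sample_id, label."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#",
                     names=["sample", "label"], dtype=str, skipinitialspace=True)
    pos = {s: i for i, s in enumerate(sample_ids)}
    try:
        idx = np.array([pos[s.strip()] for s in df["sample"]], dtype=np.intp)
    except KeyError as e:
        raise ValueError(f"{path}: unknown sample id {e.args[0]!r}") from None
    return SemiSupervisedSample(indices=idx, labels=df["label"].str.strip().to_numpy())
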