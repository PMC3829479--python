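"""Partition-agreement metrics: Rand index and adjusted Rand index.

Both are computed in O(r*c) from the r x c contingency table of the two
partitions rather than by enumerating the C(n, 2) sample pairs.  The
adjusted index is the Hubert-Arabie chance-corrected form

    ARI = (sum_ij C(n_ij, 2) - E) / (M - E)

with ``E = sum_i C(a_i, 2) * sum_j C(b_j, 2) / C(n, 2)`` and
``M = (sum_i C(a_i, 2) + sum_j C(b_j, 2)) / 2``; it equals 1 for identical
partitions and has expectation 0 under random labelings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ContingencyTable", "contingency_table", "rand_index", "adjusted_rand_index"]


@dataclass
class ContingencyTable:
    counts: np.ndarray  # (r, c) integer matrix
    row_sums: np.ndarray
    col_sums: np.ndarray
    n: int


def _as_codes(labels) -> np.ndarray:
    labels = np.asarray(getattr(labels, "labels", labels))
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def contingency_table(p1, p2) -> ContingencyTable:
    c1, c2 = _as_codes(p1), _as_codes(p2)
    if len(c1) != len(c2):
        raise ValueError(f"partition lengths differ: {len(c1)} vs {len(c2)}")
    r, c = int(c1.max()) + 1, int(c2.max()) + 1
    counts = np.bincount(c1 * c + c2, minlength=r * c).reshape(r, c)
    return ContingencyTable(
        counts=counts,
        row_sums=counts.sum(axis=1),
        col_sums=counts.sum(axis=0),
        n=len(c1),
    )


def _choose2(x: np.ndarray) -> np.ndarray:
    x = x.astype(np.int64)
    return x * (x - 1) // 2


def rand_index(p1, p2) -> float:
    """Fraction of sample pairs on which two partitions agree, in [0, 1]."""
    t = contingency_table(p1, p2)
    if t.n < 2:
        logger.warning("Rand index of a single sample is 1 by convention")
        return 1.0
    total = _choose2(np.array(t.n)).item()
    same_same = int(_choose2(t.counts).sum())
    same_1 = int(_choose2(t.row_sums).sum())
    same_2 = int(_choose2(t.col_sums).sum())
    # agreements = pairs together in both + pairs apart in both
    agree = same_same + (total - same_1 - same_2 + same_same)
    return agree / total


def adjusted_rand_index(p1, p2) -> float:
    """Hubert-Arabie chance-corrected Rand index, <= 1.

    Evaluated in exact integer arithmetic via the equivalent pair-count form
    ``2(ad - bc) / ((a+b)(b+d) + (a+c)(c+d))`` where a/b/c/d count sample
    pairs joint/disjoint in the two partitions, so printed-precision values
    like -0.5 come out exactly.
    """
    t = contingency_table(p1, p2)
    if t.n < 2:
        logger.warning("adjusted Rand index of a single sample is 1 by convention")
        return 1.0
    total = _choose2(np.array(t.n)).item()
    a = int(_choose2(t.counts).sum())  # together in both
    b = int(_choose2(t.row_sums).sum()) - a  # together in p1 only
    c = int(_choose2(t.col_sums).sum()) - a  # together in p2 only
    d = total - a - b - c  # apart in both
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0:
        # both all-singleton or both one-cluster: identical by construction
        logger.warning("degenerate partitions (max index equals expectation); ARI = 1")
        return 1.0
    return 2.0 * (a * d - b * c) / denom
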