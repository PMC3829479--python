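import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def enumerate_partitions(n: int) -> list[tuple[int, ...]]:
    """All set partitions of {0..n-1} as canonical restricted-growth labels."""
    out: list[tuple[int, ...]] = []

    def rec(prefix: list[int], m: int) -> None:
        if len(prefix) == n:
            out.append(tuple(prefix))
            return
        for v in range(m + 1):
            rec(prefix + [v], max(m, v + 1))

    rec([0], 1)
    return out


def random_constraint_set(rng, n: int, density: float = 0.1):
    """A random (possibly inconsistent) symmetric zero-diagonal constraint set."""
    from sssc import ConstraintSet

    must = np.triu((rng.random((n, n)) < density).astype(np.int8), 1)
    cannot = np.triu((rng.random((n, n)) < density).astype(np.int8), 1)
    cannot &= ~must  # raw inputs contradiction-free pairwise; propagation may reintroduce
    return ConstraintSet(must=must + must.T, cannot=cannot + cannot.T)
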