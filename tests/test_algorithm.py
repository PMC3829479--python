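import numpy as np
import pytest

from sssc import (
    ConstraintSet,
    SSSCParams,
    adjust_affinity,
    adjusted_rand_index,
    base_affinity,
    cluster_sssc,
    cluster_unsupervised,
    constraints_from_labels,
    local_scales,
    propagate_and_sanitize,
    sample_labeled_subset,
    simulate_mixture,
)
from sssc.simulate import overlapping_pair_instance

from conftest import random_constraint_set
from test_constraints import pairs_to_set


def random_affinity(rng, n):
    W = rng.random((n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    return W


def step_2b_only(W, c):
    out = W.copy()
    out[c.must.astype(bool)] = 1.0
    out[c.cannot.astype(bool)] = 0.0
    return out


class TestSSSCParams:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(K=3, alpha=2), "alpha"),
            (dict(K=3, beta=0.5), "beta"),
            (dict(K=0), "K="),
            (dict(K=2, T=0), "T="),
        ],
    )
    def test_validation(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            SSSCParams(**kwargs)


class TestAdjustAffinity:
    def test_empty_constraints_identity(self, rng):
        W = random_affinity(rng, 10)
        out = adjust_affinity(W, ConstraintSet.empty(10), alpha=0, beta=1.0)
        assert np.array_equal(out, W)

    def test_must_and_cannot_overwritten(self, rng):
        W = random_affinity(rng, 5)
        c = pairs_to_set(5, must=[(0, 1)], cannot=[(2, 3)])
        out = adjust_affinity(W, propagate_and_sanitize(c), alpha=0, beta=1.0)
        assert out[0, 1] == out[1, 0] == 1.0
        assert out[2, 3] == out[3, 2] == 0.0

    def test_cannot_anchor_penalty_hand_trace(self):
        # points a=0, b=1 cannot-linked; unconstrained k=2 with
        # W_ka = 0.9 > W_kb = 0.8: anchor c_k = a, so W_kb is divided by beta
        W = np.array(
            [
                [0.0, 0.5, 0.9],
                [0.5, 0.0, 0.8],
                [0.9, 0.8, 0.0],
            ]
        )
        c = pairs_to_set(3, cannot=[(0, 1)])
        out = adjust_affinity(W, c, alpha=0, beta=2.0)
        assert out[2, 1] == out[1, 2] == 0.4
        assert out[2, 0] == out[0, 2] == 0.9
        assert out[0, 1] == 0.0

    def test_must_anchor_copy_hand_trace(self):
        # a=0, b=1 must-linked; unconstrained k=2 nearest to a:
        # alpha=1 copies W_ak onto W_bk; alpha=0 leaves W_bk alone
        W = np.array(
            [
                [0.0, 0.5, 0.9],
                [0.5, 0.0, 0.3],
                [0.9, 0.3, 0.0],
            ]
        )
        c = pairs_to_set(3, must=[(0, 1)])
        out1 = adjust_affinity(W, c, alpha=1, beta=1.0)
        assert out1[1, 2] == out1[2, 1] == 0.9
        out0 = adjust_affinity(W, c, alpha=0, beta=1.0)
        assert out0[1, 2] == 0.3

    def test_baseline_is_step_2b_only(self, rng):
        # alpha=0, beta=1 must equal the similarity-overwriting baseline exactly
        for _ in range(100):
            n = int(rng.integers(4, 31))
            W = random_affinity(rng, n)
            c = propagate_and_sanitize(random_constraint_set(rng, n))
            out = adjust_affinity(W, c, alpha=0, beta=1.0)
            assert np.array_equal(out, step_2b_only(W, c))

    def test_range_and_symmetry_preserved(self, rng):
        for alpha in (0, 1):
            for beta in (1.0, 3.0, 50.0):
                n = 20
                W = random_affinity(rng, n)
                c = propagate_and_sanitize(random_constraint_set(rng, n))
                out = adjust_affinity(W, c, alpha=alpha, beta=beta)
                assert np.array_equal(out, out.T)
                assert np.all(np.diag(out) == 0)
                assert out.min() >= 0 and out.max() <= 1

    def test_beta_monotonically_reduces_cannot_leakage(self, rng):
        # summed affinity between the two sides of a cannot-linked pair of
        # must-components is non-increasing in beta
        X, lab = simulate_mixture(2, [20, 20], [[0, 0], [2, 0]], [1, 1], seed=5)
        sub = sample_labeled_subset(lab, 0.4, seed=6)
        c = propagate_and_sanitize(constraints_from_labels(sub, len(lab)))
        W = base_affinity(X, local_scales(X, T=5))
        side1, side2 = np.flatnonzero(lab == 1), np.flatnonzero(lab == 2)
        leaks = []
        for beta in (1.0, 2.0, 5.0, 10.0, 100.0):
            out = adjust_affinity(W, c, alpha=0, beta=beta)
            leaks.append(out[np.ix_(side1, side2)].sum())
        assert all(a >= b - 1e-12 for a, b in zip(leaks, leaks[1:]))

    def test_unsanitized_constraints_rejected(self, rng):
        W = random_affinity(rng, 4)
        c = pairs_to_set(4, must=[(0, 1)], cannot=[(0, 1)])
        with pytest.raises(ValueError, match="sanitize"):
            adjust_affinity(W, c, alpha=0, beta=1.0)

    def test_invalid_parameters(self, rng):
        W = random_affinity(rng, 4)
        c = ConstraintSet.empty(4)
        with pytest.raises(ValueError, match="beta"):
            adjust_affinity(W, c, alpha=0, beta=0.5)
        with pytest.raises(ValueError, match="alpha"):
            adjust_affinity(W, c, alpha=2, beta=1.0)


class TestClusterSSSC:
    def test_reduces_to_unsupervised_without_constraints(self):
        for seed in range(3):
            X, _ = simulate_mixture(3, [20, 20, 20], [[0, 0], [8, 0], [0, 8]], [1, 1, 1], seed=seed)
            a = cluster_sssc(
                X, ConstraintSet.empty(len(X)), SSSCParams(K=3, alpha=0, beta=1.0, seed=seed)
            )
            b = cluster_unsupervised(X, K=3, seed=seed)
            assert adjusted_rand_index(a, b) == 1.0

    def test_constraints_help_on_overlap(self):
        # heavily overlapping unequal pair: anchored adjustment beats the
        # overwrite-only baseline on average
        ours, yang = [], []
        for seed in range(20):
            X, lab = overlapping_pair_instance(seed)
            sub = sample_labeled_subset(lab, 0.5, seed=seed + 1000)
            c = propagate_and_sanitize(constraints_from_labels(sub, len(lab)))
            ours.append(
                adjusted_rand_index(
                    cluster_sssc(X, c, SSSCParams(K=4, alpha=1, beta=10.0, seed=seed)), lab
                )
            )
            yang.append(
                adjusted_rand_index(
                    cluster_sssc(X, c, SSSCParams(K=4, alpha=0, beta=1.0, seed=seed)), lab
                )
            )
        assert np.mean(ours) > np.mean(yang)

    def test_full_supervision_coclusters_must_pairs(self):
        X, lab = simulate_mixture(3, [15, 15, 15], [[0, 0], [25, 0], [0, 25]], [1, 1, 1], seed=11)
        sub = sample_labeled_subset(lab, 1.0, seed=0)
        c = propagate_and_sanitize(constraints_from_labels(sub, len(lab)))
        part = cluster_sssc(X, c, SSSCParams(K=3, alpha=1, beta=10.0, seed=0))
        for i, j in zip(*np.nonzero(np.triu(c.must, 1))):
            assert part.labels[i] == part.labels[j]

    def test_k1_shortcut(self):
        X, _ = simulate_mixture(2, [5, 5], [[0, 0], [5, 0]], [1, 1], seed=0)
        part = cluster_sssc(X, ConstraintSet.empty(10), SSSCParams(K=1))
        assert set(part.labels) == {1}
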