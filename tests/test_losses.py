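import numpy as np
import pytest

import _oracles as O
from scanchor import (
    compute_weight_schedule, loss_batch, loss_cf, loss_gas, loss_high,
    loss_low, loss_rna, total_loss,
)
from scanchor.autodiff import Tensor
from conftest import random_embedding_batch


class TestWeightSchedule:
    @pytest.mark.parametrize("K,rare,expect", [
        (10, 0.03, (0.04, 1.0, 0.2)),
        (13, 0.0, (0.01, 1.0, 2 / 13)),
        (20, 0.0, (0.02, 2.0, 0.1)),
        (5, 0.1, (0.11, 1.0, 0.4)),   # round(0.5) -> 1, half away from zero
        (2, 0.5, (0.0, 0.0, 1.0)),
    ])
    def test_printed_formulas(self, K, rare, expect):
        w1, w2, w3 = compute_weight_schedule(K, rare)
        np.testing.assert_allclose((w1, w2, w3), expect, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_weight_schedule(1, 0.0)
        with pytest.raises(ValueError):
            compute_weight_schedule(5, 1.5)


def _rand_weights(rng):
    return (float(rng.uniform(0, 0.5)), float(rng.uniform(0, 2)),
            float(rng.uniform(0, 1)))


class TestLossRna:
    def test_matches_loop_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            E, labels = random_embedding_batch(rng)
            w1, w2, w3 = _rand_weights(rng)
            got = loss_rna(Tensor(E), labels, w1, w2, w3).item()
            want = O.o_loss_rna(E, labels, w1, w2, w3)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_single_cluster_drops_separation(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(6, 3))
        one = loss_rna(Tensor(E), np.zeros(6, dtype=int), 0.4, 0.0, 0.0).item()
        want = O.o_mean_sigma_inv(E, 0.4)
        for j in range(3):
            want += O.pop_std(E[:, j]) / 3
        np.testing.assert_allclose(one, want, atol=1e-6)

    def test_doubling_separation_decreases_loss(self):
        E = np.array([[0.0, 0.0], [1.0, 0.1], [5.0, 0.0], [6.0, 0.1]])
        labels = np.array([0, 0, 1, 1])
        near = loss_rna(Tensor(E), labels, 0.5, 0.0, 0.0).item()
        E2 = E.copy()
        E2[2:, 0] += 5.0  # double the inter-cluster gap
        far = loss_rna(Tensor(E2), labels, 0.5, 0.0, 0.0).item()
        # isolate the separation term: subtract the (identical) other terms
        assert far < near


class TestLossGas:
    def test_graph_mode_matches_loop_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            E, _ = random_embedding_batch(rng)
            n, d = E.shape
            k = int(rng.integers(1, 4))
            nv = rng.normal(size=(n, k, d))
            w1, w2, w3 = _rand_weights(rng)
            got = loss_gas(Tensor(E), w1, w2, w3, mode="graph",
                           neighbor_values=nv).item()
            want = O.o_loss_gas_graph(E, nv, w1, w2, w3)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_anchored_mode_matches_loop_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            E, labels = random_embedding_batch(rng)
            groups = [np.flatnonzero(labels == k) for k in np.unique(labels)]
            w1, w2, w3 = _rand_weights(rng)
            got = loss_gas(Tensor(E), w1, w2, w3, mode="anchored",
                           anchored_groups=groups).item()
            want = O.o_loss_gas_anchored(E, groups, w1, w2, w3)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_degenerate_graph_drops_neighborhood_term(self):
        rng = np.random.default_rng(3)
        E = rng.normal(size=(5, 2))
        got = loss_gas(Tensor(E), 0.2, 0.5, 0.1, mode="graph",
                       neighbor_values=np.empty((5, 0, 2))).item()
        want = (O.o_mean_sigma_inv(E, 0.2) + O.o_cov_offdiag(E, 0.5)
                + O.o_mean_anchor(E, 0.1))
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_coincident_neighbors_zero_cohesion(self):
        E = np.ones((4, 2))
        nv = np.ones((4, 3, 2))
        got = loss_gas(Tensor(E), 0.0, 0.0, 0.0, mode="graph",
                       neighbor_values=nv).item()
        # only the guarded inverse-sigma term survives (the smoothed std
        # keeps it marginally below the hard 1/eps ceiling)
        np.testing.assert_allclose(got, 1.0 / O.EPS, rtol=0.15)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            loss_gas(Tensor(np.ones((2, 2))), 0, 0, 0, mode="bogus")


class TestAnchorLosses:
    def test_hand_computed_single_anchor(self):
        E_a = np.array([[0.0, 0.0]])
        partner = np.array([[1.0, 1.0]])
        centroid = np.array([[1.0, 1.0]])
        got = loss_high(Tensor(E_a), [0], partner, centroid, n=1, w4=1.5).item()
        np.testing.assert_allclose(got, 2.5)
        low = loss_low(Tensor(E_a), [0], partner, centroid, n=1, w4=1.5,
                       w5=0.8).item()
        np.testing.assert_allclose(low, 0.8 * 2.5)

    def test_identical_embeddings_zero(self):
        E = np.random.default_rng(0).normal(size=(3, 4))
        got = loss_high(Tensor(E), [0, 1, 2], E, E, n=3).item()
        assert got == 0.0

    def test_empty_anchor_set_zero(self):
        E = np.ones((3, 2))
        assert loss_high(Tensor(E), [], np.empty((0, 2)), np.empty((0, 2)),
                         n=3).item() == 0.0
        assert loss_low(Tensor(E), [], np.empty((0, 2)), np.empty((0, 2)),
                        n=3).item() == 0.0

    def test_w5_zero_kills_low_loss(self):
        E = np.random.default_rng(1).normal(size=(2, 3))
        got = loss_low(Tensor(E), [0], np.ones((1, 3)), np.ones((1, 3)),
                       n=2, w5=0.0).item()
        assert got == 0.0

    def test_matches_loop_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            E, _ = random_embedding_batch(rng)
            n, d = E.shape
            p = int(rng.integers(0, n + 1))
            idx = rng.choice(n, size=p, replace=False)
            partners = rng.normal(size=(p, d))
            cents = rng.normal(size=(p, d))
            w4, w5 = float(rng.uniform(0, 2)), float(rng.uniform(0, 1))
            got = loss_high(Tensor(E), idx, partners, cents, n, w4).item()
            want = O.o_loss_high(E, idx, partners, cents, n, w4)
            np.testing.assert_allclose(got, want, atol=1e-6)
            got = loss_low(Tensor(E), idx, partners, cents, n, w4, w5).item()
            want = O.o_loss_low(E, idx, partners, cents, n, w4, w5)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        E = rng.normal(size=(6, 3))
        idx = np.array([0, 2, 4])
        partners = rng.normal(size=(3, 3))
        cents = rng.normal(size=(3, 3))
        base = loss_high(Tensor(E), idx, partners, cents, 6).item()
        perm = rng.permutation(3)
        permuted = loss_high(Tensor(E), idx[perm], partners[perm],
                             cents[perm], 6).item()
        np.testing.assert_allclose(base, permuted, atol=1e-12)


class TestLossBatch:
    def test_identical_embeddings_zero(self):
        E = np.random.default_rng(0).normal(size=(4, 3))
        assert loss_batch(Tensor(E), Tensor(E.copy())).item() == 0.0

    def test_constant_offset_hand_computed(self):
        rng = np.random.default_rng(1)
        E_r = rng.normal(size=(5, 2))
        E_a = E_r + 1.0
        got = loss_batch(Tensor(E_a), Tensor(E_r), w6=0.01).item()
        np.testing.assert_allclose(got, 0.01 * 1.0, atol=1e-9)

    def test_scaling_changes_only_std_term(self):
        rng = np.random.default_rng(2)
        E_r = rng.normal(size=(8, 3))
        E_r -= E_r.mean(axis=0)  # zero-mean toy
        got = loss_batch(Tensor(2 * E_r), Tensor(E_r), w6=5.0).item()
        want = sum(O.pop_std(E_r[:, j]) for j in range(3)) / 3
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_matches_loop_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            E_a, _ = random_embedding_batch(rng)
            E_r = rng.normal(size=E_a.shape)
            w6 = float(rng.uniform(0, 1))
            got = loss_batch(Tensor(E_a), Tensor(E_r), w6).item()
            np.testing.assert_allclose(got, O.o_loss_batch(E_a, E_r, w6),
                                       atol=1e-6)

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(11)
        E_a, E_r = rng.normal(size=(2, 7, 4))
        perm = rng.permutation(7)
        a = loss_batch(Tensor(E_a), Tensor(E_r)).item()
        b = loss_batch(Tensor(E_a[perm]), Tensor(E_r[perm])).item()
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestLossCf:
    def test_perfect_prediction_is_one(self):
        P = np.eye(3)
        got = loss_cf(Tensor(P), np.array([0, 1, 2])).item()
        np.testing.assert_allclose(got, 1.0, rtol=1e-7)

    def test_hand_computed_misclassified_cell(self):
        P = np.array([[0.3, 0.7]])
        got = loss_cf(Tensor(P), np.array([0])).item()
        np.testing.assert_allclose(got, 1 / 0.3 + 0.7, rtol=1e-6)

    def test_uniform_probabilities_tie_rule(self):
        K = 4
        P = np.full((5, K), 1.0 / K)
        # all cells labelled class 0: argmax tie resolves to 0, no penalty
        got = loss_cf(Tensor(P), np.zeros(5, dtype=int)).item()
        np.testing.assert_allclose(got, K, rtol=1e-6)

    def test_matches_loop_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            n, K = int(rng.integers(2, 20)), int(rng.integers(2, 6))
            logits = rng.normal(size=(n, K))
            P = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
            y = rng.integers(0, K, size=n)
            got = loss_cf(Tensor(P), y).item()
            np.testing.assert_allclose(got, O.o_loss_cf(P, y), atol=1e-6)


class TestTotalLoss:
    def test_sum_and_additivity(self):
        terms = {"a": Tensor(1.5), "b": Tensor(2.0), "c": Tensor(0.25)}
        assert total_loss(terms).item() == 3.75
        terms["high"] = Tensor(0.0)
        assert total_loss(terms).item() == 3.75

    def test_nonfinite_term_named(self):
        with pytest.raises(FloatingPointError, match="bad_term"):
            total_loss({"ok": Tensor(1.0), "bad_term": Tensor(np.inf)})


class TestGradients:
    """Finite-difference check of autodiff gradients for every term."""

    @staticmethod
    def _fd_check(f, X, atol=1e-4):
        t = Tensor(X, requires_grad=True)
        out = f(t)
        out.backward()
        h = 1e-6
        num = np.zeros_like(X)
        for i in range(X.shape[0]):
            for j in range(X.shape[1]):
                Xp, Xm = X.copy(), X.copy()
                Xp[i, j] += h
                Xm[i, j] -= h
                num[i, j] = (f(Tensor(Xp)).item() - f(Tensor(Xm)).item()) / (2 * h)
        np.testing.assert_allclose(t.grad, num, atol=atol)

    def test_all_terms(self):
        rng = np.random.default_rng(42)
        E = rng.normal(size=(6, 3))
        y = np.array([0, 0, 1, 1, 2, 2])
        nv = rng.normal(size=(6, 2, 3))
        partners = rng.normal(size=(2, 3))
        cents = rng.normal(size=(2, 3))
        E_r = rng.normal(size=(6, 3))
        self._fd_check(lambda t: loss_rna(t, y, 0.3, 1.2, 0.4), E)
        self._fd_check(
            lambda t: loss_gas(t, 0.3, 1.2, 0.4, "graph", neighbor_values=nv), E)
        self._fd_check(
            lambda t: loss_gas(t, 0.3, 1.2, 0.4, "anchored",
                               anchored_groups=[[0, 1], [2, 3, 4]]), E)
        self._fd_check(lambda t: loss_high(t, [1, 3], partners, cents, 6), E)
        self._fd_check(lambda t: loss_low(t, [1, 3], partners, cents, 6), E)
        self._fd_check(lambda t: loss_batch(t, Tensor(E_r)), E)

    def test_cf_gradient(self):
        rng = np.random.default_rng(43)
        logits = rng.normal(size=(5, 3))
        y = np.array([0, 1, 2, 0, 1])
        from scanchor.network import softmax

        self._fd_check(lambda t: loss_cf(softmax(t), y), logits)
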