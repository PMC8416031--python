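"""Linear-chain CRF against brute-force path enumeration and finite differences."""

import itertools

import numpy as np
import pytest

from somnostage.crf import (
    CrfParams,
    class_weighted_gradients,
    class_weighted_nll,
    crf_gradients,
    forward_backward,
    log_partition,
    nll_loss,
    path_score,
    viterbi,
)
from somnostage.stages import N_STAGES


def enumerate_paths(T):
    return itertools.product(range(N_STAGES), repeat=T)


def brute_log_partition(E, params, w=None):
    scores = [path_score(E, np.array(y), params, w) for y in enumerate_paths(len(E))]
    m = max(scores)
    return m + np.log(sum(np.exp(s - m) for s in scores))


def brute_marginals(E, params, w=None):
    T = len(E)
    logZ = brute_log_partition(E, params, w)
    gamma = np.zeros((T, N_STAGES))
    xi = np.zeros((N_STAGES, N_STAGES))
    for y in enumerate_paths(T):
        p = np.exp(path_score(E, np.array(y), params, w) - logZ)
        for t, k in enumerate(y):
            gamma[t, k] += p
        for t in range(1, T):
            xi[y[t - 1], y[t]] += p
    return gamma, xi


def random_instance(rng, T):
    E = rng.normal(size=(T, N_STAGES))
    params = CrfParams(
        transitions=rng.normal(size=(N_STAGES, N_STAGES)),
        start=rng.normal(size=N_STAGES),
        end=rng.normal(size=N_STAGES),
    )
    return E, params


class TestPathScore:
    def test_single_epoch_unit_weights(self):
        E = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
        params = CrfParams(start=np.arange(5.0), end=np.full(5, 0.5))
        assert path_score(E, [2], params) == pytest.approx(3.0 + 2.0 + 0.5)

    def test_zero_transitions_sums_emissions(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(6, 5))
        y = rng.integers(0, 5, size=6)
        assert path_score(E, y, CrfParams()) == pytest.approx(
            E[np.arange(6), y].sum()
        )

    def test_class_weights_scale_gold_emissions(self):
        # Hand-set 3-epoch example with the imbalance weights (1, 6, 1, 2, 1).
        E = np.array(
            [[0.5, 1.0, 0.0, 0.0, 0.0], [0.2, 2.0, 0.1, 0.0, 0.0], [0.0, 0.0, 0.0, 3.0, 0.0]]
        )
        A = np.arange(25.0).reshape(5, 5) / 10.0
        params = CrfParams(transitions=A)
        w = np.array([1.0, 6.0, 1.0, 2.0, 1.0])
        y = np.array([1, 1, 3])
        expected = 6 * 1.0 + 6 * 2.0 + 2 * 3.0 + A[1, 1] + A[1, 3]
        assert path_score(E, y, params, w) == pytest.approx(expected)

    def test_invalid_stage_index_raises(self):
        with pytest.raises(ValueError):
            path_score(np.zeros((2, 5)), [0, 7], CrfParams())


class TestLogPartition:
    def test_uniform_case_is_T_log5(self):
        for T in (1, 3, 10):
            assert log_partition(np.zeros((T, 5)), CrfParams()) == pytest.approx(
                T * np.log(5)
            )

    @pytest.mark.parametrize("T", [1, 2, 3, 4])
    def test_matches_brute_force(self, T):
        rng = np.random.default_rng(100 + T)
        for _ in range(5):
            E, params = random_instance(rng, T)
            w = rng.uniform(0.5, 3.0, size=5)
            assert log_partition(E, params, w) == pytest.approx(
                brute_log_partition(E, params, w), abs=1e-10
            )

    def test_emission_shift_identity(self):
        rng = np.random.default_rng(7)
        E, params = random_instance(rng, 5)
        c = 1.73
        E2 = E.copy()
        E2[2] += c
        assert log_partition(E2, params) == pytest.approx(
            log_partition(E, params) + c
        )


class TestForwardBackward:
    def test_uniform_marginals(self):
        gamma, xi, _ = forward_backward(np.zeros((4, 5)), CrfParams())
        np.testing.assert_allclose(gamma, 0.2, atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        E, params = random_instance(rng, 20)
        gamma, _, _ = forward_backward(E, params)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("T", [1, 2, 3, 5])
    def test_matches_enumeration(self, T):
        rng = np.random.default_rng(200 + T)
        E, params = random_instance(rng, T)
        w = rng.uniform(0.5, 2.0, size=5)
        gamma, xi, _ = forward_backward(E, params, w)
        g_ref, xi_ref = brute_marginals(E, params, w)
        np.testing.assert_allclose(gamma, g_ref, atol=1e-9)
        np.testing.assert_allclose(xi, xi_ref, atol=1e-9)

    def test_marginal_argmax_can_differ_from_viterbi(self):
        # Construct by search: per-epoch most-probable stages need not form
        # the single best path.
        rng = np.random.default_rng(11)
        for _ in range(500):
            E, params = random_instance(rng, 3)
            gamma, _, _ = forward_backward(E, params)
            path, _ = viterbi(E, params)
            if np.any(gamma.argmax(axis=1) != path):
                return
        pytest.fail("no instance found where marginal argmax differs from Viterbi")


class TestViterbi:
    def test_zero_transitions_is_per_epoch_argmax(self):
        rng = np.random.default_rng(5)
        E = rng.normal(size=(12, 5))
        path, score = viterbi(E, CrfParams())
        np.testing.assert_array_equal(path, E.argmax(axis=1))
        assert score == pytest.approx(E.max(axis=1).sum())

    @pytest.mark.parametrize("T", [2, 3, 4])
    def test_matches_brute_force_best_path(self, T):
        rng = np.random.default_rng(300 + T)
        for _ in range(5):
            E, params = random_instance(rng, T)
            path, score = viterbi(E, params)
            best = max(
                (path_score(E, np.array(y), params), y) for y in enumerate_paths(T)
            )
            assert score == pytest.approx(best[0], abs=1e-10)
            assert tuple(path) == best[1]

    def test_tie_broken_toward_lower_index(self):
        E = np.zeros((3, 5))
        path, _ = viterbi(E, CrfParams())
        np.testing.assert_array_equal(path, 0)

    def test_forbidden_transition_avoided(self):
        # Strongly negative W->N3 score forces decoded paths around it even
        # when emissions pull toward W then N3.
        E = np.array([[5.0, 0, 0, 0, 0], [0, 0, 0, 5.0, 0], [0, 0, 0, 5.0, 0]])
        A = np.zeros((5, 5))
        A[0, 3] = -100.0
        path, _ = viterbi(E, CrfParams(transitions=A))
        transitions = list(zip(path[:-1], path[1:]))
        assert (0, 3) not in transitions


class TestNll:
    def test_loss_nonnegative_at_viterbi_path(self):
        rng = np.random.default_rng(17)
        E, params = random_instance(rng, 6)
        path, _ = viterbi(E, params)
        assert nll_loss(E, path, params) >= 0.0

    def test_loss_vanishes_with_dominant_emissions(self):
        y = np.array([0, 2, 4, 1])
        E = np.full((4, 5), -50.0)
        E[np.arange(4), y] = 50.0
        assert nll_loss(E, y, CrfParams()) == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_posterior(self):
        rng = np.random.default_rng(23)
        E, params = random_instance(rng, 3)
        y = rng.integers(0, 5, size=3)
        logZ = brute_log_partition(E, params)
        expected = logZ - path_score(E, y, params)
        assert nll_loss(E, y, params) == pytest.approx(expected, abs=1e-10)

    def test_log_partition_dominates_any_path(self):
        rng = np.random.default_rng(29)
        E, params = random_instance(rng, 4)
        lz = log_partition(E, params)
        for y in enumerate_paths(4):
            assert lz >= path_score(E, np.array(y), params)


class TestGradients:
    def _finite_diff(self, f, x, eps=1e-6):
        g = np.zeros_like(x, dtype=float)
        it = np.nditer(x, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = x[idx]
            x[idx] = orig + eps
            fp = f()
            x[idx] = orig - eps
            fm = f()
            x[idx] = orig
            g[idx] = (fp - fm) / (2 * eps)
            it.iternext()
        return g

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(31)
        E, params = random_instance(rng, 4)
        y = rng.integers(0, 5, size=4)
        w = np.array([1.0, 6.0, 1.0, 2.0, 1.0])
        dE, dA, dstart, dend, _ = crf_gradients(E, y, params, w)

        np.testing.assert_allclose(
            dE, self._finite_diff(lambda: nll_loss(E, y, params, w), E), atol=1e-6
        )
        np.testing.assert_allclose(
            dA,
            self._finite_diff(lambda: nll_loss(E, y, params, w), params.transitions),
            atol=1e-6,
        )
        np.testing.assert_allclose(
            dstart,
            self._finite_diff(lambda: nll_loss(E, y, params, w), params.start),
            atol=1e-6,
        )
        np.testing.assert_allclose(
            dend,
            self._finite_diff(lambda: nll_loss(E, y, params, w), params.end),
            atol=1e-6,
        )

    def test_upweighting_n1_amplifies_gold_emission_gradient(self):
        # Finite-difference check: the loss gradient w.r.t. the gold-N1
        # emission grows in magnitude when w[N1] is raised.
        rng = np.random.default_rng(37)
        E, params = random_instance(rng, 5)
        y = np.array([0, 1, 1, 2, 0])
        unit = np.ones(5)
        heavy = np.array([1.0, 6.0, 1.0, 2.0, 1.0])
        g_unit, *_ = crf_gradients(E, y, params, unit)
        g_heavy, *_ = crf_gradients(E, y, params, heavy)
        n1_rows = np.where(y == 1)[0]
        assert np.abs(g_heavy[n1_rows, 1]).sum() > np.abs(g_unit[n1_rows, 1]).sum()


class TestGoldWeightedLoss:
    """The training loss: weights on the gold path's emission term only."""

    def test_unit_weights_reduce_to_standard_nll(self):
        rng = np.random.default_rng(41)
        E, params = random_instance(rng, 5)
        y = rng.integers(0, 5, size=5)
        assert class_weighted_nll(E, y, params) == pytest.approx(
            nll_loss(E, y, params), abs=1e-12
        )

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(43)
        E, params = random_instance(rng, 4)
        y = rng.integers(0, 5, size=4)
        w = np.array([1.0, 6.0, 1.0, 2.0, 1.0])
        dE, dA, dstart, dend, loss = class_weighted_gradients(E, y, params, w)
        assert loss == pytest.approx(class_weighted_nll(E, y, params, w), abs=1e-12)

        eps = 1e-6
        for arr, grad in [
            (E, dE),
            (params.transitions, dA),
            (params.start, dstart),
            (params.end, dend),
        ]:
            it = np.nditer(arr, flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                fp = class_weighted_nll(E, y, params, w)
                arr[idx] = orig - eps
                fm = class_weighted_nll(E, y, params, w)
                arr[idx] = orig
                assert grad[idx] == pytest.approx((fp - fm) / (2 * eps), abs=1e-6)
                it.iternext()

    def test_upweighted_stage_gets_stronger_upward_push(self):
        # dE[t, y_t] = P(y_t) - w[y_t]: gold-N1 epochs are pushed up about
        # w-fold harder than under unit weights.
        rng = np.random.default_rng(47)
        E, params = random_instance(rng, 5)
        y = np.array([0, 1, 1, 2, 0])
        g_unit, *_ = class_weighted_gradients(E, y, params)
        g_heavy, *_ = class_weighted_gradients(
            E, y, params, np.array([1.0, 6.0, 1.0, 2.0, 1.0])
        )
        n1 = np.where(y == 1)[0]
        assert np.all(g_heavy[n1, 1] < g_unit[n1, 1])  # more negative = pushed up
        np.testing.assert_allclose(g_heavy[n1, 1], g_unit[n1, 1] - 5.0, atol=1e-12)
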