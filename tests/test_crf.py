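"""Exact-inference checks of the linear-chain CRF against brute-force
enumeration over all tag paths."""

import itertools

import numpy as np
import pytest

from endcnn import crf


def enumerate_paths(n, m):
    return itertools.product(range(m), repeat=n)


def brute_force(P, T):
    """Reference by enumeration: per-path scores, logZ and argmax path
    (ties toward the lexicographically smallest path, matching the
    lowest-tag-index backpointer rule)."""
    n, m = P.shape
    scores = {}
    for y in enumerate_paths(n, m):
        s = T[0, y[0]] + P[0, y[0]]
        for i in range(1, n):
            s += T[y[i - 1] + 1, y[i]] + P[i, y[i]]
        scores[y] = s
    logZ = float(np.logaddexp.reduce(np.array(list(scores.values()))))
    best = min(scores, key=lambda y: (-scores[y], y))
    return scores, logZ, best


@pytest.fixture(scope="module")
def instances():
    rng = np.random.default_rng(42)
    out = []
    for _ in range(200):
        n = int(rng.integers(1, 7))
        m = int(rng.integers(1, 6))
        out.append((rng.uniform(-2, 2, (n, m)), rng.uniform(-2, 2, (m + 1, m))))
    return out


class TestPathScore:
    def test_zero_scores_give_zero(self):
        P, T = np.zeros((3, 2)), np.zeros((3, 2))
        for y in enumerate_paths(3, 2):
            assert crf.path_score(P, T, np.array(y)) == 0.0

    def test_length_one_is_start_plus_emission(self, rng):
        P = rng.normal(size=(1, 4))
        T = rng.normal(size=(5, 4))
        for j in range(4):
            assert crf.path_score(P, T, np.array([j])) == pytest.approx(T[0, j] + P[0, j])

    def test_matches_enumeration(self, rng):
        P = rng.integers(-3, 4, (3, 2)).astype(float)
        T = rng.integers(-3, 4, (3, 2)).astype(float)
        scores, _, _ = brute_force(P, T)
        for y, s in scores.items():
            assert crf.path_score(P, T, np.array(y)) == pytest.approx(s)

    def test_out_of_range_tag_rejected(self):
        P, T = np.zeros((2, 2)), np.zeros((3, 2))
        with pytest.raises(ValueError):
            crf.path_score(P, T, np.array([0, 5]))


class TestLogPartition:
    def test_uniform_case_is_log_m(self):
        m = 5
        P = np.zeros((1, m))
        T = np.zeros((m + 1, m))
        assert crf.log_partition(P, T) == pytest.approx(np.log(m))

    def test_matches_enumeration_within_1e8(self, rng):
        P = rng.uniform(-2, 2, (4, 3))
        T = rng.uniform(-2, 2, (4, 3))
        _, logZ, _ = brute_force(P, T)
        assert crf.log_partition(P, T) == pytest.approx(logZ, abs=1e-8)

    def test_dominates_every_path_score(self, rng):
        P = rng.uniform(-2, 2, (4, 3))
        T = rng.uniform(-2, 2, (4, 3))
        logZ = crf.log_partition(P, T)
        for y in enumerate_paths(4, 3):
            assert logZ >= crf.path_score(P, T, np.array(y))

    def test_numerically_stable_at_large_scores(self):
        P = np.full((5, 3), 1e3)
        T = np.full((4, 3), 1e3)
        val = crf.log_partition(P, T)
        assert np.isfinite(val)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            crf.log_partition(np.zeros((0, 2)), np.zeros((3, 2)))


class TestLogLikelihood:
    def test_probabilities_normalize(self, rng):
        P = rng.uniform(-2, 2, (4, 3))
        T = rng.uniform(-2, 2, (4, 3))
        total = sum(
            np.exp(crf.log_likelihood(P, T, np.array(y)))
            for y in enumerate_paths(4, 3)
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_single_tag_degenerate_case_is_certain(self, rng):
        P = rng.normal(size=(4, 1))
        T = rng.normal(size=(2, 1))
        assert crf.log_likelihood(P, T, np.zeros(4, dtype=int)) == pytest.approx(0.0)

    def test_never_positive(self, instances):
        for P, T in instances[:50]:
            n, m = P.shape
            y = np.zeros(n, dtype=int)
            assert crf.log_likelihood(P, T, y) <= 1e-12


class TestViterbi:
    def test_zero_transitions_reduce_to_argmax(self, rng):
        P = rng.normal(size=(6, 4))
        T = np.zeros((5, 4))
        path, _ = crf.viterbi_decode(P, T)
        np.testing.assert_array_equal(path, P.argmax(axis=1))

    def test_all_equal_scores_pick_lowest_indices(self):
        P = np.ones((4, 3))
        T = np.ones((4, 3))
        path, _ = crf.viterbi_decode(P, T)
        np.testing.assert_array_equal(path, np.zeros(4, dtype=int))

    def test_agrees_with_enumeration_on_200_instances(self, instances):
        for P, T in instances:
            scores, logZ, best = brute_force(P, T)
            path, score = crf.viterbi_decode(P, T)
            assert tuple(path) == best
            assert score == pytest.approx(scores[best], abs=1e-8)
            assert score == pytest.approx(crf.path_score(P, T, path), abs=1e-10)
            assert crf.log_partition(P, T) == pytest.approx(logZ, abs=1e-8)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        n, m = 4, 3
        P = rng.uniform(-1, 1, (n, m))
        T = rng.uniform(-1, 1, (m + 1, m))
        y = rng.integers(0, m, n)
        _, dP, dT = crf.neg_log_likelihood_grads(P, T, y)
        eps = 1e-6
        for A, dA in ((P, dP), (T, dT)):
            num = np.zeros_like(A)
            for idx in np.ndindex(A.shape):
                A[idx] += eps
                up = -crf.log_likelihood(P, T, y)
                A[idx] -= 2 * eps
                dn = -crf.log_likelihood(P, T, y)
                A[idx] += eps
                num[idx] = (up - dn) / (2 * eps)
            np.testing.assert_allclose(num, dA, atol=1e-6)

    def test_marginals_sum_to_one_per_position(self, rng):
        P = rng.uniform(-2, 2, (5, 4))
        T = rng.uniform(-2, 2, (5, 4))
        unary, pairwise, start, _ = crf.forward_backward_marginals(P, T)
        np.testing.assert_allclose(unary.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(pairwise.sum(axis=(1, 2)), 1.0, atol=1e-10)
        np.testing.assert_allclose(start.sum(), 1.0, atol=1e-10)
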