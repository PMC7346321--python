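"""Linear-chain CRF scoring, exact inference and gradients.

Conventions
-----------
``P`` is the ``n x m`` emission-score matrix (``P[i, j]`` the score of tag
``j`` at position ``i``). ``T`` is an ``(m + 1) x m`` matrix: row 0 holds
the start scores for beginning a sequence in each tag, and ``T[i + 1, j]``
the score of transitioning from tag ``i`` to tag ``j``.

The score of a tag path ``y`` is the sum of its transition and emission
scores; path probabilities are the softmax of path scores over all ``m**n``
paths. ``log_partition`` computes the log of that normalizer with the
forward recursion in log space; ``viterbi_decode`` returns the argmax path,
breaking score ties toward the lowest tag index.
"""

from __future__ import annotations

import numpy as np


def _lse(a: np.ndarray, axis: int | None = None) -> np.ndarray:
    """log-sum-exp along ``axis``, streamlined for the hot recursions."""
    if axis is None:
        amax = a.max()
        return float(np.log(np.exp(a - amax).sum()) + amax)
    amax = a.max(axis=axis, keepdims=True)
    out = np.log(np.exp(a - amax).sum(axis=axis, keepdims=True)) + amax
    return out.squeeze(axis)


def _check(P: np.ndarray, T: np.ndarray) -> tuple[int, int]:
    n, m = P.shape
    if T.shape != (m + 1, m):
        raise ValueError(f"T must be (m+1) x m = {(m + 1, m)}, got {T.shape}")
    if n < 1:
        raise ValueError("empty sequence")
    return n, m


def path_score(P: np.ndarray, T: np.ndarray, y: np.ndarray) -> float:
    """Score of one tag path: start + transitions + emissions."""
    n, m = _check(P, T)
    y = np.asarray(y, dtype=np.int64)
    if len(y) != n:
        raise ValueError("path length does not match emission rows")
    if y.min() < 0 or y.max() >= m:
        raise ValueError("tag index out of range")
    score = T[0, y[0]] + P[0, y[0]]
    for i in range(1, n):
        score += T[y[i - 1] + 1, y[i]] + P[i, y[i]]
    return float(score)


def log_partition(P: np.ndarray, T: np.ndarray) -> float:
    """log sum over all tag paths of exp(path score), forward recursion."""
    n, _ = _check(P, T)
    alpha = T[0] + P[0]
    for i in range(1, n):
        alpha = _lse(alpha[:, None] + T[1:], axis=0) + P[i]
    return float(_lse(alpha))


def log_likelihood(P: np.ndarray, T: np.ndarray, y: np.ndarray) -> float:
    """log p(y | X) = path_score - log_partition; always <= 0."""
    return path_score(P, T, y) - log_partition(P, T)


def viterbi_decode(P: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum-score tag path and its score.

    Ties are broken toward the lowest tag index at every backpointer
    (``argmax`` returns the first maximum).
    """
    n, m = _check(P, T)
    delta = T[0] + P[0]
    back = np.zeros((n, m), dtype=np.int64)
    for i in range(1, n):
        cand = delta[:, None] + T[1:]  # cand[prev, cur]
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], np.arange(m)] + P[i]
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path, float(delta[path[-1]])


def forward_backward_marginals(
    P: np.ndarray, T: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Unary marginals, pairwise marginals, start marginals, and log Z.

    Returns ``(unary, pairwise, start, logZ)`` with ``unary[i, j] =
    p(y_i = j)``, ``pairwise[i, a, b] = p(y_i = a, y_{i+1} = b)`` for
    ``i < n - 1``, and ``start[j] = p(y_1 = j)`` (equal to ``unary[0]``).
    """
    n, m = _check(P, T)
    la = np.zeros((n, m))  # log alpha
    la[0] = T[0] + P[0]
    for i in range(1, n):
        la[i] = _lse(la[i - 1][:, None] + T[1:], axis=0) + P[i]
    lb = np.zeros((n, m))  # log beta
    for i in range(n - 2, -1, -1):
        lb[i] = _lse(T[1:] + (P[i + 1] + lb[i + 1])[None, :], axis=1)
    logZ = float(_lse(la[-1]))
    unary = np.exp(la + lb - logZ)
    pairwise = np.zeros((max(n - 1, 0), m, m))
    for i in range(n - 1):
        pairwise[i] = np.exp(
            la[i][:, None] + T[1:] + (P[i + 1] + lb[i + 1])[None, :] - logZ
        )
    return unary, pairwise, unary[0].copy(), logZ


def neg_log_likelihood_grads(
    P: np.ndarray, T: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Negative log-likelihood and its gradients w.r.t. ``P`` and ``T``.

    d(-log p)/dP = unary marginals - path indicators; the ``T`` gradient is
    the expected minus observed transition (and start) counts.
    """
    n, m = _check(P, T)
    y = np.asarray(y, dtype=np.int64)
    unary, pairwise, start, logZ = forward_backward_marginals(P, T)
    score = path_score(P, T, y)
    dP = unary.copy()
    dP[np.arange(n), y] -= 1.0
    dT = np.zeros_like(T)
    dT[0] = start
    dT[0, y[0]] -= 1.0
    dT[1:] = pairwise.sum(axis=0)
    for i in range(1, n):
        dT[y[i - 1] + 1, y[i]] -= 1.0
    return float(logZ - score), dP, dT
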