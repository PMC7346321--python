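"""Exact CRF inference on a tiny instance, checked against enumeration.

The extractor's CRF scores a tag path as the sum of transition and
emission scores; the probability of a path is its softmax over all m**n
paths. On a 3-position, 2-tag instance we can enumerate all 8 paths and
confirm that the forward recursion (log-partition) and Viterbi agree with
brute force.
"""

import itertools

import numpy as np

from endcnn import log_likelihood, log_partition, path_score, viterbi_decode

rng = np.random.default_rng(0)
P = rng.uniform(-1, 1, (3, 2))   # emission scores: positions x tags
T = rng.uniform(-1, 1, (3, 2))   # transition scores: start row + 2x2

scores = {y: path_score(P, T, np.array(y))
          for y in itertools.product(range(2), repeat=3)}
logZ = np.log(sum(np.exp(s) for s in scores.values()))
print(f"log-partition (forward recursion): {log_partition(P, T):.6f}")
print(f"log-partition (enumeration):       {logZ:.6f}")

path, score = viterbi_decode(P, T)
best = max(scores, key=scores.get)
print(f"Viterbi path {tuple(path)} score {score:.4f}; enumeration argmax {best}")

total = sum(np.exp(log_likelihood(P, T, np.array(y))) for y in scores)
print(f"sum of path probabilities: {total:.10f} (should be 1)")
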