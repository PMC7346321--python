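"""Character vocabulary and skip-gram character embeddings.

Character vectors are trained with skip-gram and negative sampling over a
plain character corpus. A dictionary of risk-factor surface strings can be
injected into the training stream as additional short sentences, so the
characters of each risk factor co-occur tightly and end up close in the
embedding space. Training is single-threaded and fully determined by the
seed.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
PAD_INDEX = 0
UNK_INDEX = 1


@dataclass(frozen=True)
class Vocabulary:
    """Character <-> index bijection with reserved PAD=0 and UNK=1."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tokens[:2] != (PAD_TOKEN, UNK_TOKEN):
            raise ValueError("vocabulary must start with PAD, UNK")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(self, "_idx", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._idx  # type: ignore[attr-defined]

    def index(self, token: str) -> int:
        """Index of ``token``, falling back to UNK."""
        return self._idx.get(token, UNK_INDEX)  # type: ignore[attr-defined]

    def token(self, index: int) -> str:
        return self.tokens[index]

    def encode(self, chars: Iterable[str]) -> np.ndarray:
        return np.array([self.index(c) for c in chars], dtype=np.int64)


def build_vocab(corpus: Iterable[str], min_count: int = 1) -> Vocabulary:
    """Build a character vocabulary from sequences of characters.

    Characters with frequency >= ``min_count`` are kept, ordered by
    frequency descending then codepoint ascending, after PAD and UNK.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: Counter[str] = Counter()
    for sent in corpus:
        counts.update(sent)
    kept = sorted(
        (c for c, n in counts.items() if n >= min_count),
        key=lambda c: (-counts[c], c),
    )
    return Vocabulary((PAD_TOKEN, UNK_TOKEN, *kept))


def embed_sequence(
    chars: Sequence[str], vocab: Vocabulary, matrix: np.ndarray
) -> np.ndarray:
    """Look up the embedding row of each character; OOV maps to the UNK row.

    Returns an ``n x d`` matrix for an ``n``-character input.
    """
    if matrix.shape[0] != len(vocab):
        raise ValueError("matrix rows do not match vocabulary size")
    idx = vocab.encode(chars)
    return matrix[idx].copy() if len(idx) else np.zeros((0, matrix.shape[1]))


def train_char_embeddings(
    corpus: Sequence[str],
    dictionary: Sequence[str] = (),
    dim: int = 100,
    window: int = 5,
    negatives: int = 5,
    epochs: int = 5,
    seed: int = 0,
    lr: float = 0.025,
    dictionary_repeat: int = 10,
    vocab: Vocabulary | None = None,
) -> tuple[Vocabulary, np.ndarray]:
    """Train skip-gram character embeddings with negative sampling.

    The training stream is the corpus sentences followed by each dictionary
    entry repeated ``dictionary_repeat`` times, so characters within a
    risk-factor surface form tight co-occurrence neighbourhoods. Negative
    samples are drawn from the unigram distribution raised to 3/4. The PAD
    row is frozen at zero and never trained.

    The returned vectors are the mean of each token's input and output
    (context) vectors, with the common mean direction removed
    (mean-centering over trained rows): skip-gram spaces on small corpora
    are strongly anisotropic, and centering makes cosine similarity
    reflect co-occurrence rather than the shared drift direction.

    Returns (vocabulary, v x dim matrix). Fixed seed gives a bit-identical
    matrix.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    sentences = [s for s in corpus if s]
    sentences += [d for d in dictionary if d] * dictionary_repeat
    if not sentences:
        raise ValueError("nothing to train on: empty corpus and dictionary")
    if vocab is None:
        vocab = build_vocab(sentences, min_count=1)

    rng = np.random.default_rng(seed)
    v = len(vocab)
    W_in = (rng.random((v, dim)) - 0.5) / dim
    W_out = np.zeros((v, dim))
    W_in[PAD_INDEX] = 0.0

    counts = np.zeros(v)
    encoded = [vocab.encode(s) for s in sentences]
    for idx in encoded:
        np.add.at(counts, idx, 1.0)
    noise = counts**0.75
    noise[PAD_INDEX] = 0.0
    if noise.sum() == 0:
        raise ValueError("nothing to train on: no known characters")
    noise /= noise.sum()

    total_steps = max(1, epochs * sum(len(s) for s in encoded))
    step = 0
    for _epoch in range(epochs):
        for idx in encoded:
            n = len(idx)
            for pos in range(n):
                step += 1
                alpha = lr * max(1e-4, 1.0 - step / total_steps)
                w = 1 + int(rng.integers(window))  # dynamic window, word2vec style
                lo, hi = max(0, pos - w), min(n, pos + w + 1)
                center = idx[pos]
                context = np.concatenate([idx[lo:pos], idx[pos + 1 : hi]])
                if center == PAD_INDEX or len(context) == 0:
                    continue
                for ctx in context:
                    if ctx == PAD_INDEX:
                        continue
                    targets = np.empty(negatives + 1, dtype=np.int64)
                    targets[0] = ctx
                    targets[1:] = rng.choice(v, size=negatives, p=noise)
                    labels = np.zeros(negatives + 1)
                    labels[0] = 1.0
                    vin = W_in[center]
                    vout = W_out[targets]
                    scores = 1.0 / (1.0 + np.exp(-vout @ vin))
                    g = (labels - scores) * alpha
                    W_in[center] = vin + g @ vout
                    W_out[targets] += np.outer(g, vin)
    combined = (W_in + W_out) / 2.0
    if len(vocab) > 2:
        combined[2:] -= combined[2:].mean(axis=0)
    combined[PAD_INDEX] = 0.0
    return vocab, combined
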