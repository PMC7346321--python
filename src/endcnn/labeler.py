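"""BiLSTM-CRF risk-factor extractor.

A sentence of characters is embedded (pretrained skip-gram vectors,
fine-tuned during training), encoded by a bidirectional LSTM, mapped to
per-tag confidence scores ``e_t = tanh(W_e h_t)``, and decoded by a
linear-chain CRF whose transition matrix is trained jointly. Training
maximizes the log-probability of the gold tag path; inference is Viterbi.
Decoded BIO tag paths are folded into risk-factor mentions, repairing an
``I-x`` that lacks a compatible predecessor into ``B-x``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import crf
from .embeddings import Vocabulary
from .lstm import BiLSTMParams, LSTMParams, bilstm_backward, bilstm_forward
from .optim import clip_gradients, learning_rate
from .tags import DEFAULT_SCHEME, OUTSIDE, TagScheme
from .types import AnnotatedSentence, RiskFactorMention


@dataclass
class LabelerConfig:
    """Training configuration for the extractor.

    ``hidden_size`` is the per-direction LSTM width; the learning-rate
    schedule is ``lr * dr ** (step / ds)`` with gradient-norm clipping.
    """

    hidden_size: int = 100
    embedding_dim: int = 100
    lr: float = 0.015
    decay_rate: float = 0.99
    decay_steps: int = 500
    clip_norm: float = 5.0
    epochs: int = 10
    momentum: float = 0.9
    finetune_embeddings: bool = True


def emission_scores(H: np.ndarray, W_e: np.ndarray) -> np.ndarray:
    """Per-position tag scores ``tanh(W_e h_t)``; an ``n x m`` matrix with
    entries strictly inside (-1, 1)."""
    if H.shape[1] != W_e.shape[1]:
        raise ValueError(
            f"hidden width {H.shape[1]} does not match W_e columns {W_e.shape[1]}"
        )
    return np.tanh(H @ W_e.T)


class SequenceLabeler:
    """Trained BiLSTM-CRF model over a character vocabulary and tag scheme."""

    def __init__(
        self,
        vocab: Vocabulary,
        scheme: TagScheme,
        config: LabelerConfig,
        embeddings: np.ndarray,
        seed: int = 0,
    ) -> None:
        self.vocab = vocab
        self.scheme = scheme
        self.config = config
        m = scheme.num_tags
        rng = np.random.default_rng(seed)
        self.E = np.array(embeddings, dtype=np.float64)
        if self.E.shape != (len(vocab), config.embedding_dim):
            raise ValueError("embedding matrix shape does not match vocab/config")
        self.bilstm = BiLSTMParams.init(config.embedding_dim, config.hidden_size, rng)
        self.W_e = rng.uniform(-0.1, 0.1, size=(m, 2 * config.hidden_size))
        self.T = np.zeros((m + 1, m))

    # --- parameter plumbing -------------------------------------------------

    def _params(self) -> dict[str, np.ndarray]:
        p = {
            "Wf": self.bilstm.forward.W, "bf": self.bilstm.forward.b,
            "Wb": self.bilstm.backward.W, "bb": self.bilstm.backward.b,
            "W_e": self.W_e, "T": self.T,
        }
        if self.config.finetune_embeddings:
            p["E"] = self.E
        return p

    # --- forward / loss -----------------------------------------------------

    def scores(self, chars: str) -> np.ndarray:
        """Emission-score matrix P for a sentence."""
        X = self.E[self.vocab.encode(chars)]
        H, _ = bilstm_forward(X, self.bilstm)
        return emission_scores(H, self.W_e)

    def _loss_and_grads(
        self, chars: str, y: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        idx = self.vocab.encode(chars)
        X = self.E[idx]
        H, cache = bilstm_forward(X, self.bilstm)
        A = H @ self.W_e.T
        P = np.tanh(A)
        loss, dP, dT = crf.neg_log_likelihood_grads(P, self.T, y)
        dA = dP * (1.0 - P**2)
        dW_e = dA.T @ H
        dH = dA @ self.W_e
        dX, dlstm = bilstm_backward(dH, cache, self.bilstm)
        grads = {
            "Wf": dlstm.forward.W, "bf": dlstm.forward.b,
            "Wb": dlstm.backward.W, "bb": dlstm.backward.b,
            "W_e": dW_e, "T": dT,
        }
        if self.config.finetune_embeddings:
            dE = np.zeros_like(self.E)
            np.add.at(dE, idx, dX)
            grads["E"] = dE
        return loss, grads

    # --- inference ----------------------------------------------------------

    def predict_tags(self, chars: str) -> list[str]:
        if len(chars) == 0:
            return []
        P = self.scores(chars)
        path, _ = crf.viterbi_decode(P, self.T)
        tags = self.scheme.tags
        return [tags[i] for i in path]

    def extract(self, chars: str) -> list[RiskFactorMention]:
        return decode_mentions(chars, self.predict_tags(chars), self.scheme)

    # --- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            E=self.E, Wf=self.bilstm.forward.W, bf=self.bilstm.forward.b,
            Wb=self.bilstm.backward.W, bb=self.bilstm.backward.b,
            W_e=self.W_e, T=self.T,
            meta=np.frombuffer(json.dumps({
                "tokens": list(self.vocab.tokens),
                "codes": list(self.scheme.codes),
                "config": vars(self.config),
            }).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SequenceLabeler":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        vocab = Vocabulary(tuple(meta["tokens"]))
        scheme = TagScheme(tuple(meta["codes"]))
        config = LabelerConfig(**meta["config"])
        model = cls(vocab, scheme, config, data["E"], seed=0)
        model.bilstm = BiLSTMParams(
            LSTMParams(data["Wf"], data["bf"]), LSTMParams(data["Wb"], data["bb"])
        )
        model.W_e = data["W_e"]
        model.T = data["T"]
        return model


def train_labeler(
    corpus: list[AnnotatedSentence],
    vocab: Vocabulary,
    embeddings: np.ndarray,
    config: LabelerConfig | None = None,
    seed: int = 0,
    scheme: TagScheme = DEFAULT_SCHEME,
    log_every: int = 0,
) -> tuple[SequenceLabeler, list[float]]:
    """Train a BiLSTM-CRF extractor; returns (model, per-epoch mean loss).

    Training is per-sentence stochastic gradient descent with momentum, the
    exponential learning-rate schedule and gradient-norm clipping from the
    config. Plain SGD (rather than an adaptive method) matters here: the
    emission scores are tanh-bounded, and adaptive per-parameter step sizes
    keep pushing pre-activations deep into the saturated tails where the
    gradient dies; SGD steps shrink with the gradient and are self-limiting
    near saturation. Deterministic for a fixed seed on a single thread.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    config = config or LabelerConfig()
    tag_index = {t: i for i, t in enumerate(scheme.tags)}
    encoded: list[np.ndarray] = []
    for sent in corpus:
        try:
            encoded.append(np.array([tag_index[t] for t in sent.tags], dtype=np.int64))
        except KeyError as exc:
            raise ValueError(f"unknown tag {exc.args[0]!r} in training corpus") from None

    model = SequenceLabeler(vocab, scheme, config, embeddings, seed=seed)
    params = model._params()
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    rng = np.random.default_rng(seed + 1)
    losses: list[float] = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(corpus))
        total = 0.0
        for j in order:
            sent = corpus[j]
            if len(sent) == 0:
                continue
            step += 1
            loss, grads = model._loss_and_grads(sent.chars, encoded[j])
            clip_gradients(grads, config.clip_norm)
            alpha = learning_rate(
                config.lr, config.decay_rate, config.decay_steps, step
            )
            for k, g in grads.items():
                velocity[k] = config.momentum * velocity[k] + g
                params[k] -= alpha * velocity[k]
            total += loss
        losses.append(total / len(corpus))
        if log_every and (epoch + 1) % log_every == 0:
            print(f"[labeler] epoch {epoch + 1}/{config.epochs} "
                  f"mean NLL {losses[-1]:.4f}")
    return model, losses


def decode_mentions(
    chars: str, tags: list[str] | tuple[str, ...], scheme: TagScheme = DEFAULT_SCHEME
) -> list[RiskFactorMention]:
    """Fold a BIO tag path into risk-factor mentions.

    Maximal B-led runs of one composite code become mentions. An ``I-x``
    whose predecessor is neither ``B-x`` nor ``I-x`` is repaired to ``B-x``
    (starting a new mention), which preserves recall over dropping it.
    """
    if len(chars) != len(tags):
        raise ValueError("chars/tags length mismatch")
    mentions: list[RiskFactorMention] = []
    start: int | None = None
    code: str | None = None

    def close(end: int) -> None:
        nonlocal start, code
        if start is not None and code is not None:
            mentions.append(
                RiskFactorMention.from_code(code, start, end, chars[start:end])
            )
        start, code = None, None

    for i, tag in enumerate(tags):
        if tag == OUTSIDE:
            close(i)
            continue
        prefix, this_code = tag[:1], scheme.tag_code(tag)
        if prefix == "B" or this_code != code:
            close(i)  # repair: orphan I-x opens a new mention
            start, code = i, this_code
    close(len(tags))
    return mentions
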