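"""Synthetic EMR-like corpus generator.

Real annotated EMR corpora for this task are private, so this module
generates documents with the statistical structure both models assume:
filler characters interleaved with planted risk-factor mentions that carry
BIO tags with composite type+temporal codes, and a binary document label
produced by a known planted rule (at least ``theta`` distinct risk-factor
types whose temporal attribute lies in an active set).

The alphabet is an abstract one — lowercase letters as filler, per-type
uppercase/digit characters for mention surfaces — because both
architectures are script-agnostic and no realistic clinical text is
fabricated. Temporal attributes are not deducible from a mention surface
alone, so each mention is preceded by a one-character temporal marker
(tagged O), standing in for the contextual temporal cues of real clinical
narrative; the extractor must read that context to label temporality.

Generation is O(total characters) and bit-reproducible for a fixed seed
(single numpy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tags import ATEMPORAL_TYPES, RISK_FACTORS
from .types import AnnotatedSentence, LabeledDocument, RiskFactorMention, mentions_to_tags

_CONTENT_CHARS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"

#: one-character context markers per temporal attribute (tagged O)
TEMPORAL_MARKERS: dict[str, str] = {"C": "!", "D": "@", "A": "#", "B": "$", "N": "%"}


def default_lexicon() -> dict[str, tuple[str, ...]]:
    """Fixed surface lexicon: each risk-factor type owns three disjoint
    content characters and three short surface strings over them."""
    lex: dict[str, tuple[str, ...]] = {}
    for i, (code, _name) in enumerate(RISK_FACTORS):
        a, b, c = _CONTENT_CHARS[3 * i : 3 * i + 3]
        lex[code] = (a + b, b + c, a + c + b)
    return lex


@dataclass(frozen=True)
class PlantedRule:
    """Deterministic labeling rule on a document's mention multiset:
    label 1 iff the number of DISTINCT risk-factor types whose temporal
    attribute is in ``active_set`` reaches ``threshold``."""

    threshold: int = 3
    active_set: frozenset[str] = frozenset({"C", "D"})

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")


def planted_rule(
    mentions: list[RiskFactorMention] | tuple[RiskFactorMention, ...],
    rule: PlantedRule = PlantedRule(),
) -> int:
    active_types = {m.rf_type for m in mentions if m.temporal in rule.active_set}
    return int(len(active_types) >= rule.threshold)


@dataclass(frozen=True)
class SynthConfig:
    """Generative model of the synthetic corpus.

    Filler runs are geometric (support >= 1) with success probability
    ``filler_p``; the mention count per document is Poisson(``mention_rate``);
    temporal attributes follow ``temporal_probs`` (Age/Gender are always N).
    ``prevalence`` is steered by rejection sampling with at most
    ``max_tries`` draws per document.
    """

    n_docs: int = 659
    filler_alphabet: str = "abcdefghijklmnopqrst"
    filler_p: float = 0.35
    mention_rate: float = 5.0
    lexicon: dict[str, tuple[str, ...]] = field(default_factory=default_lexicon)
    temporal_probs: dict[str, float] = field(
        default_factory=lambda: {"C": 0.35, "D": 0.25, "A": 0.2, "B": 0.2}
    )
    rule: PlantedRule = field(default_factory=PlantedRule)
    prevalence: float = 0.8
    seed: int = 13
    max_tries: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.filler_p < 1 or not 0 < self.prevalence < 1:
            raise ValueError("probabilities must lie in (0, 1)")
        if self.mention_rate <= 0:
            raise ValueError("mention_rate must be positive")
        for code, surfaces in self.lexicon.items():
            if not surfaces:
                raise ValueError(f"empty lexicon for type {code!r}")


@dataclass(frozen=True)
class GeneratedDocument:
    sentence: AnnotatedSentence
    mentions: tuple[RiskFactorMention, ...]
    document: LabeledDocument


@dataclass(frozen=True)
class SplitCorpus:
    train: tuple[GeneratedDocument, ...]
    dev: tuple[GeneratedDocument, ...]
    test: tuple[GeneratedDocument, ...]

    @property
    def all(self) -> tuple[GeneratedDocument, ...]:
        return self.train + self.dev + self.test


def _filler(config: SynthConfig, rng: np.random.Generator) -> str:
    n = int(rng.geometric(config.filler_p))
    idx = rng.integers(len(config.filler_alphabet), size=n)
    return "".join(config.filler_alphabet[i] for i in idx)


def generate_document(
    config: SynthConfig, rng: np.random.Generator
) -> GeneratedDocument:
    """One synthetic document: filler runs interleaved with planted
    mentions, gold BIO tags, and the planted-rule label."""
    types = [code for code, _ in RISK_FACTORS]
    t_codes = list(config.temporal_probs)
    t_probs = np.array([config.temporal_probs[t] for t in t_codes], dtype=float)
    t_probs = t_probs / t_probs.sum()

    k = int(rng.poisson(config.mention_rate))
    parts: list[str] = [_filler(config, rng)]
    mentions: list[RiskFactorMention] = []
    pos = len(parts[0])
    for _ in range(k):
        rf = types[int(rng.integers(len(types)))]
        temporal = "N" if rf in ATEMPORAL_TYPES else t_codes[int(rng.choice(len(t_codes), p=t_probs))]
        surfaces = config.lexicon[rf]
        surface = surfaces[int(rng.integers(len(surfaces)))]
        marker = TEMPORAL_MARKERS[temporal]
        parts.append(marker)
        pos += 1
        mentions.append(
            RiskFactorMention(rf, temporal, pos, pos + len(surface), surface)
        )
        parts.append(surface)
        pos += len(surface)
        run = _filler(config, rng)
        parts.append(run)
        pos += len(run)
    text = "".join(parts)
    tags = mentions_to_tags(mentions, len(text))
    label = planted_rule(mentions, config.rule)
    return GeneratedDocument(
        AnnotatedSentence(text, tags),
        tuple(mentions),
        LabeledDocument(text, label, tuple(mentions)),
    )


def sample_documents(
    config: SynthConfig, n: int, rng: np.random.Generator | None = None
) -> list[GeneratedDocument]:
    """Draw ``n`` documents at the configured prevalence by rejection
    sampling, shuffled; raises if the class quota cannot be filled within
    ``max_tries`` draws per document."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    want_pos = round(n * config.prevalence)
    want_neg = n - want_pos
    out: list[GeneratedDocument] = []
    tries = 0
    while want_pos + want_neg > 0:
        doc = generate_document(config, rng)
        tries += 1
        lbl = doc.document.label
        if lbl == 1 and want_pos > 0:
            out.append(doc)
            want_pos -= 1
        elif lbl == 0 and want_neg > 0:
            out.append(doc)
            want_neg -= 1
        if tries > config.max_tries * n:
            raise RuntimeError(
                f"rejection sampling exhausted: prevalence {config.prevalence} "
                "infeasible under the planted rule"
            )
    idx = rng.permutation(len(out))
    return [out[i] for i in idx]


def _split_sizes(n: int) -> tuple[int, int, int]:
    # default split proportions 461 : 66 : 132
    train = round(n * 461 / 659)
    dev = round(n * 66 / 659)
    return train, dev, n - train - dev


def generate_corpus(config: SynthConfig) -> SplitCorpus:
    """Generate a corpus with disjoint train/dev/test splits.

    The class balance is steered to ``prevalence`` by rejection sampling;
    if ``max_tries`` draws cannot produce a document of the still-needed
    class, the prevalence/rule combination is reported as infeasible
    rather than silently biased. Every document's label is consistent with
    the planted rule by construction.
    """
    if config.n_docs < 10:
        raise ValueError("n_docs must be >= 10")
    rng = np.random.default_rng(config.seed)
    want_pos = round(config.n_docs * config.prevalence)
    want_neg = config.n_docs - want_pos
    docs: list[GeneratedDocument] = []
    while len(docs) < config.n_docs:
        for _try in range(config.max_tries):
            doc = generate_document(config, rng)
            lbl = doc.document.label
            if (lbl == 1 and want_pos > 0) or (lbl == 0 and want_neg > 0):
                docs.append(doc)
                if lbl == 1:
                    want_pos -= 1
                else:
                    want_neg -= 1
                break
        else:
            raise RuntimeError(
                "rejection sampling exhausted: prevalence "
                f"{config.prevalence} infeasible under the planted rule"
            )
    order = rng.permutation(len(docs))
    shuffled = [docs[i] for i in order]
    n_train, n_dev, n_test = _split_sizes(config.n_docs)
    return SplitCorpus(
        tuple(shuffled[:n_train]),
        tuple(shuffled[n_train : n_train + n_dev]),
        tuple(shuffled[n_train + n_dev :]),
    )
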