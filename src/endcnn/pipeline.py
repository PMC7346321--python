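"""End-to-end glue: normalize text, extract mentions, pack classifier
units, predict CVD, and score both stages.

The classifier does not read raw text. Each extracted mention is packed
with its label into a fixed-width *unit of 7* cells: up to six surface
characters (truncated or PAD-padded) followed by one label token encoding
``B-<code>``. With region size k=7 one region covers exactly one
(mention, label) unit; k=14 covers two adjacent units.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from .classifier import EnDCNNModel
from .embeddings import PAD_INDEX, Vocabulary
from .labeler import SequenceLabeler
from .tags import DEFAULT_SCHEME, TagScheme
from .types import RiskFactorMention

UNIT_WIDTH = 7
#: substitution for configured missing-value markers
MISSING_TOKEN = "∅"


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f_score: float


@dataclass(frozen=True)
class Prediction:
    label: int
    probability: float  # probability of the CVD class
    no_evidence: bool = False


def normalize_document(
    raw: str, missing_markers: tuple[str, ...] = ("NA", "N/A", "null")
) -> str:
    """Minimal text normalizer: unicode NFC, control characters stripped,
    whitespace runs collapsed to one space, and whitespace-delimited
    missing-value markers replaced by a single MISSING token."""
    text = unicodedata.normalize("NFC", raw)
    cleaned = []
    for c in text:
        if c in "\t\n\r":
            cleaned.append(" ")
        elif unicodedata.category(c).startswith("C"):
            continue
        else:
            cleaned.append(c)
    tokens = "".join(cleaned).split()
    tokens = [MISSING_TOKEN if t in missing_markers else t for t in tokens]
    return " ".join(tokens)


def unit_vocabulary(
    char_vocab: Vocabulary, scheme: TagScheme = DEFAULT_SCHEME
) -> Vocabulary:
    """Extended vocabulary over characters plus one ``B-<code>`` label token
    per composite code (PAD and UNK preserved at 0 and 1)."""
    label_tokens = tuple(f"B-{code}" for code in scheme.codes)
    return Vocabulary((*char_vocab.tokens, *label_tokens))


def mentions_to_units(
    mentions: list[RiskFactorMention],
    vocab: Vocabulary,
    cell_width: int = UNIT_WIDTH,
) -> np.ndarray:
    """Pack mentions (ordered by start offset) into fixed-width units.

    Each unit is ``cell_width`` indices: the first ``cell_width - 1``
    surface characters (truncated/PAD-padded), then the label token for
    ``B-<code>``. Unknown mention codes map to the UNK token rather than
    failing.
    """
    out: list[int] = []
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        surface = [vocab.index(c) for c in m.surface[: cell_width - 1]]
        surface += [PAD_INDEX] * (cell_width - 1 - len(surface))
        out.extend(surface)
        out.append(vocab.index(f"B-{m.code}"))
    return np.array(out, dtype=np.int64)


def predict_cvd(
    raw_text: str,
    labeler: SequenceLabeler,
    classifier: EnDCNNModel,
    unit_vocab: Vocabulary,
) -> Prediction:
    """normalize -> extract -> pack units -> classify.

    A document from which no mention is extracted carries no evidence for
    the classifier; by convention it is predicted no-CVD with the
    ``no_evidence`` flag set.
    """
    text = normalize_document(raw_text)
    mentions = labeler.extract(text)
    if not mentions:
        return Prediction(label=0, probability=0.0, no_evidence=True)
    units = mentions_to_units(mentions, unit_vocab)
    probs = classifier.forward(units)
    return Prediction(label=int(np.argmax(probs)), probability=float(probs[1]))


def entity_prf(
    gold: list[list[RiskFactorMention]],
    pred: list[list[RiskFactorMention]],
) -> Metrics:
    """Micro-averaged exact-match entity scores over aligned documents.

    A predicted mention counts as correct iff its span, risk-factor type
    and temporal attribute all match a gold mention. Accuracy is reported
    as the exact-match rate over all gold and predicted mentions
    (|matches| / |union|).
    """
    if len(gold) != len(pred):
        raise ValueError("gold and pred document lists differ in length")
    tp = fp = fn = 0
    for g_doc, p_doc in zip(gold, pred):
        g_keys = [(m.start, m.end, m.rf_type, m.temporal) for m in g_doc]
        if len(set(g_keys)) != len(g_keys):
            raise ValueError("duplicate gold mention spans")
        g_set = set(g_keys)
        p_set = {(m.start, m.end, m.rf_type, m.temporal) for m in p_doc}
        tp += len(g_set & p_set)
        fp += len(p_set - g_set)
        fn += len(g_set - p_set)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = tp + fp + fn
    accuracy = tp / denom if denom else 1.0
    return Metrics(accuracy, precision, recall, f)


def classification_metrics(
    gold: list[int] | np.ndarray, pred: list[int] | np.ndarray
) -> Metrics:
    """Accuracy over all documents plus precision/recall/F on the positive
    (CVD) class."""
    gold = np.asarray(gold, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if gold.shape != pred.shape:
        raise ValueError("gold and pred differ in length")
    acc = float(accuracy_score(gold, pred))
    p, r, f, _ = precision_recall_fscore_support(
        gold, pred, labels=[1], average="micro", zero_division=0
    )
    return Metrics(acc, float(p), float(r), float(f))
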