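"""Readers and writers for the on-disk formats the pipeline touches.

Formats
-------
* Annotated corpus: UTF-8 text, one ``char<TAB>tag`` per line, blank line
  between sentences (CoNLL-style two-column format).
* Documents: JSON lines, one object per line with ``text`` and ``label``
  fields (and optionally ``mentions``).
* Embeddings: word2vec text dialect — optional ``count dim`` header, then
  one ``token v1 ... vd`` line per vocabulary entry.

All files are UTF-8 without BOM; numeric fields use ``.`` as the decimal
separator regardless of locale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .tags import DEFAULT_SCHEME, TagScheme
from .types import AnnotatedSentence, LabeledDocument, RiskFactorMention


class CorpusFormatError(ValueError):
    """Raised on malformed corpus, document or embedding files."""


def read_annotated_corpus(
    path: str | Path, scheme: TagScheme = DEFAULT_SCHEME
) -> list[AnnotatedSentence]:
    """Parse a two-column character/tag file into sentences.

    Raises :class:`CorpusFormatError` naming the offending line for a wrong
    column count or an unknown tag string.
    """
    sentences: list[AnnotatedSentence] = []
    chars: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        if chars:
            sentences.append(AnnotatedSentence("".join(chars), tuple(tags)))
            chars.clear()
            tags.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                flush()
                continue
            cols = line.split("\t")
            if len(cols) != 2 or len(cols[0]) != 1:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 'char<TAB>tag', got {line!r}"
                )
            ch, tag = cols
            if not scheme.is_valid_tag(tag):
                raise CorpusFormatError(f"{path}:{lineno}: unknown tag {tag!r}")
            chars.append(ch)
            tags.append(tag)
    flush()
    return sentences


def write_annotated_corpus(
    sentences: list[AnnotatedSentence], path: str | Path
) -> None:
    """Write sentences in the two-column format read by
    :func:`read_annotated_corpus`.

    A literal tab or newline inside ``chars`` cannot be represented in this
    format and is rejected.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for ch, tag in zip(sent.chars, sent.tags):
                if ch in ("\t", "\n"):
                    raise CorpusFormatError(
                        "tab/newline characters cannot be written in the "
                        "two-column corpus format"
                    )
                fh.write(f"{ch}\t{tag}\n")
            fh.write("\n")


def read_documents(path: str | Path) -> list[LabeledDocument]:
    """Read JSON-lines documents with ``text`` and ``label`` fields."""
    docs: list[LabeledDocument] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: invalid JSON: {exc}") from None
            if "text" not in obj or "label" not in obj:
                raise CorpusFormatError(
                    f"{path}:{lineno}: missing required field 'text' or 'label'"
                )
            label = obj["label"]
            if label not in (0, 1, True, False):
                raise CorpusFormatError(
                    f"{path}:{lineno}: label must be 0 or 1, got {label!r}"
                )
            mentions = None
            if obj.get("mentions") is not None:
                mentions = tuple(
                    RiskFactorMention(
                        m["type"], m["temporal"], m["start"], m["end"], m["surface"]
                    )
                    for m in obj["mentions"]
                )
            docs.append(LabeledDocument(obj["text"], int(label), mentions))
    return docs


def write_documents(docs: list[LabeledDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            obj: dict = {"text": doc.text, "label": doc.label}
            if doc.mentions is not None:
                obj["mentions"] = [
                    {
                        "type": m.rf_type,
                        "temporal": m.temporal,
                        "start": m.start,
                        "end": m.end,
                        "surface": m.surface,
                    }
                    for m in doc.mentions
                ]
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def write_mentions(mentions: list[RiskFactorMention], path: str | Path) -> None:
    """One structured record per mention (type, temporal, span, surface)."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "type": m.rf_type,
                        "temporal": m.temporal,
                        "start": m.start,
                        "end": m.end,
                        "surface": m.surface,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_embeddings_text(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read word2vec text-format embeddings.

    Returns (tokens, matrix) with matrix row ``i`` the vector of
    ``tokens[i]``. The ``count dim`` header is optional; without it the
    dimension is inferred from the first row. Duplicate tokens and
    inconsistent dimensions are format errors.
    """
    tokens: list[str] = []
    rows: list[list[float]] = []
    dim: int | None = None
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines:
        head = lines[0].split(" ")
        if len(head) == 2:
            try:
                _count, dim = int(head[0]), int(head[1])
                start = 1
            except ValueError:
                pass
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line:
            continue
        parts = line.split(" ")
        token, vec = parts[0], parts[1:]
        if token in seen:
            raise CorpusFormatError(f"{path}:{lineno}: duplicate token {token!r}")
        seen.add(token)
        if dim is None:
            dim = len(vec)
        elif len(vec) != dim:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected {dim} values, got {len(vec)}"
            )
        tokens.append(token)
        rows.append([float(x) for x in vec])
    matrix = np.asarray(rows, dtype=np.float64).reshape(len(tokens), dim or 0)
    return tokens, matrix


def write_embeddings_text(
    tokens: list[str], matrix: np.ndarray, path: str | Path
) -> None:
    """Write embeddings in word2vec text format with a ``count dim`` header."""
    if len(tokens) != matrix.shape[0]:
        raise ValueError("token count does not match matrix rows")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{matrix.shape[0]} {matrix.shape[1]}\n")
        for token, row in zip(tokens, matrix):
            fh.write(token + " " + " ".join(repr(float(x)) for x in row) + "\n")
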