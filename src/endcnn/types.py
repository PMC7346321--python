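"""Core record types shared across the extraction/prediction pipeline."""

from __future__ import annotations

from dataclasses import dataclass

from .tags import DEFAULT_SCHEME, OUTSIDE, TagScheme, split_code


@dataclass(frozen=True)
class AnnotatedSentence:
    """A character sequence with one BIO tag per character."""

    chars: str
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.chars) != len(self.tags):
            raise ValueError(
                f"chars/tags length mismatch: {len(self.chars)} != {len(self.tags)}"
            )
        object.__setattr__(self, "tags", tuple(self.tags))

    def validate(self, scheme: TagScheme = DEFAULT_SCHEME) -> None:
        for t in self.tags:
            if not scheme.is_valid_tag(t):
                raise ValueError(f"unknown tag {t!r}")

    def __len__(self) -> int:
        return len(self.chars)


@dataclass(frozen=True)
class RiskFactorMention:
    """An extracted risk-factor span with its temporal attribute.

    ``start``/``end`` are a 0-based half-open character span.
    """

    rf_type: str
    temporal: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    @property
    def code(self) -> str:
        return self.rf_type + self.temporal

    @classmethod
    def from_code(cls, code: str, start: int, end: int, surface: str) -> "RiskFactorMention":
        rf, temporal = split_code(code)
        return cls(rf, temporal, start, end, surface)


@dataclass(frozen=True)
class LabeledDocument:
    """A free-text record with a binary CVD label (1 = CVD)."""

    text: str
    label: int
    mentions: tuple[RiskFactorMention, ...] | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.mentions is not None:
            object.__setattr__(self, "mentions", tuple(self.mentions))


def mentions_to_tags(
    mentions: list[RiskFactorMention] | tuple[RiskFactorMention, ...],
    length: int,
) -> tuple[str, ...]:
    """BIO tag sequence covering the given non-overlapping mentions."""
    tags = [OUTSIDE] * length
    for m in sorted(mentions, key=lambda m: m.start):
        if m.end > length:
            raise ValueError(f"mention span [{m.start}, {m.end}) exceeds length {length}")
        for i in range(m.start, m.end):
            if tags[i] != OUTSIDE:
                raise ValueError("overlapping mentions")
            tags[i] = ("B-" if i == m.start else "I-") + m.code
    return tuple(tags)
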