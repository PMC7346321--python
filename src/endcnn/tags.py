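"""Tag scheme for character-level risk-factor annotation.

Twelve cardiovascular risk factors are annotated per character with BIO
tags. Each entity code is a composite of a risk-factor code and a
single-letter temporal attribute: C(ontinue), D(uring), A(fter), B(efore).
Age and Gender carry no temporal information and combine only with the
placeholder attribute N(one). The default scheme therefore has
10 x 4 + 2 = 42 composite codes and 2 x 42 + 1 = 85 tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: (code, human-readable name) for the twelve risk factors.
RISK_FACTORS: tuple[tuple[str, str], ...] = (
    ("O2", "Overweight/Obesity"),
    ("Hy", "Hypertension"),
    ("Di", "Diabetes"),
    ("Dy", "Dyslipidemia"),
    ("CKD", "Chronic kidney disease"),
    ("At", "Atherosis"),
    ("OSAS", "Obstructive sleep apnea syndrome"),
    ("Sm", "Smoking"),
    ("A2", "Alcohol abuse"),
    ("FH", "Family history of CVD"),
    ("Age", "Age"),
    ("Gen", "Gender"),
)

#: Temporal attributes; N is reserved for Age and Gender.
TEMPORAL_ATTRIBUTES: tuple[str, ...] = ("C", "D", "A", "B", "N")

#: Risk factors that carry no temporal attribute.
ATEMPORAL_TYPES: frozenset[str] = frozenset({"Age", "Gen"})

OUTSIDE = "O"


def composite_codes() -> list[str]:
    """All valid composite entity codes, e.g. ``HyC``, ``AgeN``."""
    codes = []
    for rf, _ in RISK_FACTORS:
        if rf in ATEMPORAL_TYPES:
            codes.append(rf + "N")
        else:
            codes.extend(rf + t for t in ("C", "D", "A", "B"))
    return codes


def split_code(code: str) -> tuple[str, str]:
    """Split a composite code into (risk-factor type, temporal attribute).

    The temporal attribute is always the final character.
    """
    rf, temporal = code[:-1], code[-1]
    if temporal not in TEMPORAL_ATTRIBUTES:
        raise ValueError(f"invalid temporal attribute in code {code!r}")
    if rf not in {c for c, _ in RISK_FACTORS}:
        raise ValueError(f"unknown risk-factor type in code {code!r}")
    if (rf in ATEMPORAL_TYPES) != (temporal == "N"):
        raise ValueError(f"temporal attribute {temporal!r} not allowed for {rf!r}")
    return rf, temporal


@dataclass(frozen=True)
class TagScheme:
    """BIO tag inventory over the composite entity codes.

    Tag index 0 is the outside tag ``O``; each code contributes a ``B-`` and
    an ``I-`` tag in code order.  The indexing is part of the contract: CRF
    score matrices are laid out against it.
    """

    codes: tuple[str, ...] = field(default_factory=lambda: tuple(composite_codes()))

    @property
    def tags(self) -> list[str]:
        out = [OUTSIDE]
        for code in self.codes:
            out.append(f"B-{code}")
            out.append(f"I-{code}")
        return out

    @property
    def num_tags(self) -> int:
        return 1 + 2 * len(self.codes)

    def tag_index(self, tag: str) -> int:
        try:
            return self._index()[tag]
        except KeyError:
            raise ValueError(f"unknown tag {tag!r}") from None

    def _index(self) -> dict[str, int]:
        # frozen dataclass: cache on first use
        cache = self.__dict__.get("_idx")
        if cache is None:
            cache = {t: i for i, t in enumerate(self.tags)}
            object.__setattr__(self, "_idx", cache)
        return cache

    def is_valid_tag(self, tag: str) -> bool:
        return tag in self._index()

    def tag_code(self, tag: str) -> str | None:
        """Composite code of a B-/I- tag, or None for the outside tag."""
        if tag == OUTSIDE:
            return None
        return tag[2:]


DEFAULT_SCHEME = TagScheme()
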