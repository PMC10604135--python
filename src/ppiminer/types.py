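"""Core data types shared across the pipeline stages.

Token indices are 0-based everywhere; spans are half-open ``[start, end)``.
The entity tag set is exactly ``{"P", "O"}`` — P for protein-name tokens,
O for everything else; no BIO/BILOU prefixes are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

TAG_PROTEIN = "P"
TAG_OTHER = "O"
VALID_TAGS = frozenset({TAG_PROTEIN, TAG_OTHER})

MASK_FIRST = "PROT1"
MASK_SECOND = "PROT2"


@dataclass(frozen=True)
class Token:
    """A single token with an optional part-of-speech tag."""

    text: str
    pos: str = ""

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("Token text must be non-empty")
        if any(ch.isspace() for ch in self.text):
            raise ValueError(f"Token text contains whitespace: {self.text!r}")


@dataclass(frozen=True)
class ProteinMention:
    """A protein-name span over sentence tokens, half-open ``[start, end)``."""

    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid mention span [{self.start}, {self.end})")


@dataclass
class LabeledSentence:
    """A tokenized sentence with a binary PPI label and protein mentions.

    ``label`` is 1 when the sentence asserts a relationship between two of
    its protein mentions, 0 otherwise; a positive label therefore requires
    at least two mentions.
    """

    tokens: list[Token]
    label: int
    mentions: list[ProteinMention] = field(default_factory=list)
    pmid: str = ""

    def validate(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        n = len(self.tokens)
        spans = sorted((m.start, m.end) for m in self.mentions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("mentions overlap")
        for m in self.mentions:
            if m.end > n:
                raise ValueError(f"mention span [{m.start}, {m.end}) exceeds sentence length {n}")
            joined = " ".join(t.text for t in self.tokens[m.start : m.end])
            if m.surface != joined:
                raise ValueError(f"mention surface {m.surface!r} != covered tokens {joined!r}")
        if self.label == 1 and len(self.mentions) < 2:
            raise ValueError("a positive sentence requires at least two mentions")

    @property
    def texts(self) -> list[str]:
        return [t.text for t in self.tokens]


@dataclass
class MaskedInstance:
    """A classifier training instance with one protein pair masked.

    The first mention of the pair (in token order) is replaced by the single
    token ``PROT1`` and the second by ``PROT2``; any third-party mentions
    are left verbatim.
    """

    tokens: list[str]
    label: int
    source: LabeledSentence
    pair: tuple[int, int]

    def validate(self) -> None:
        for mask in (MASK_FIRST, MASK_SECOND):
            if self.tokens.count(mask) != 1:
                raise ValueError(f"expected exactly one {mask} token")


@dataclass
class TaggedSentence:
    """A token sequence with per-token entity tags from ``{P, O}``."""

    tokens: list[Token]
    tags: list[str]

    def __post_init__(self) -> None:
        if len(self.tags) != len(self.tokens):
            raise ValueError("tags and tokens must have the same length")
        bad = set(self.tags) - VALID_TAGS
        if bad:
            raise ValueError(f"invalid tags {sorted(bad)}; allowed: P, O")


@dataclass
class DatasetSplit:
    """A seeded 60/40 train/test partition of a sentence list."""

    train: list
    test: list
    seed: int
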