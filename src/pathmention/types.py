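"""Core span/annotation data model shared by every pipeline stage.

All offsets are 0-based, half-open ``[start, end)`` character offsets counted
in Unicode code points of the full document text.  One convention everywhere
means every annotation round-trips exactly: ``document.text[span.start:span.end]``
always equals the annotated surface string.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

ANN_TYPES = frozenset({"pathway_mention", "gene_mention", "keyword"})
SOURCES = frozenset({"dictionary", "rule", "merged", "gold"})


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval ``[start, end)`` with ``end > start >= 0``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"span start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"span end must exceed start, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class Token:
    """A surface token with its character span and (optional) Penn Treebank tag."""

    text: str
    span: Span
    pos: Optional[str] = None

    def with_pos(self, pos: str) -> "Token":
        return replace(self, pos=pos)


@dataclass(frozen=True)
class Sentence:
    span: Span
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        prev_end = self.span.start
        for tok in self.tokens:
            if tok.span.start < prev_end or tok.span.end > self.span.end:
                raise ValueError(
                    f"token span [{tok.span.start}, {tok.span.end}) violates sentence "
                    f"ordering within [{self.span.start}, {self.span.end})"
                )
            prev_end = tok.span.end


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    sentences: tuple[Sentence, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        prev_end = 0
        for sent in self.sentences:
            if sent.span.start < prev_end or sent.span.end > len(self.text):
                raise ValueError(f"sentence spans out of order in document {self.doc_id!r}")
            prev_end = sent.span.end

    @property
    def tokens(self) -> tuple[Token, ...]:
        return tuple(tok for sent in self.sentences for tok in sent.tokens)


@dataclass(frozen=True)
class Annotation:
    """A typed, optionally scored character span with provenance.

    ``score`` is mandatory for dictionary matches (the SoftTFIDF similarity) and
    absent for rule hits; ``entry_id`` links dictionary matches back to the
    dictionary entry they matched.
    """

    doc_id: str
    span: Span
    surface: str
    ann_type: str = "pathway_mention"
    score: Optional[float] = None
    source: str = "dictionary"
    entry_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ann_type not in ANN_TYPES:
            raise ValueError(f"unknown annotation type {self.ann_type!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown annotation source {self.source!r}")
        if self.source == "dictionary" and self.score is None:
            raise ValueError("dictionary annotations must carry a SoftTFIDF score")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")
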