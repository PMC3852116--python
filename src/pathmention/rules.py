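"""Keyword-anchored backward/forward rules gated on gene/protein mentions.

The rule component complements soft dictionary matching: it finds pathway
keyword anchors ("pathway", "signalling cascade", ...), extends each anchor
leftwards to the nearest determiner / separator / preposition / wh-word /
verb, optionally extends rightwards through pathway verb phrases ("regulated
by ...") up to the next punctuation, and keeps only segments that fully
contain at least one gene/protein mention.  Gene mentions come from any
recognizer implementing ``tag(document) -> [Annotation]``; a deterministic
lexicon + morphology recognizer ships with the package, and externally
produced gene annotations (e.g. from a CRF tagger) can be imported from the
standoff TSV format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence

from .resources import default_gene_lexicon, default_stopwords
from .text import STOP_CLASSES, is_punctuation, token_class, tokenize
from .types import Annotation, Document, Sentence, Span

__all__ = [
    "KeywordSet",
    "RuleSegment",
    "GeneRecognizer",
    "LexiconGeneRecognizer",
    "ImportedAnnotationRecognizer",
    "RuleEngineError",
    "DEFAULT_VERB_PHRASES",
    "find_keywords",
    "backward_extend",
    "forward_extend",
    "apply_rules",
    "load_gene_lexicon",
]


class RuleEngineError(RuntimeError):
    pass


_DEFAULT_BASE = (
    "pathway",
    "pathways",
    "signalling",
    "signaling",
    "transduction",
    "cascade",
    "cascades",
    "network",
    "networks",
)

_DEFAULT_COMBINATIONS = (
    "signal transduction pathways",
    "signal transduction pathway",
    "signal transduction",
    "signalling pathways",
    "signalling pathway",
    "signaling pathways",
    "signaling pathway",
    "signalling cascades",
    "signalling cascade",
    "signaling cascades",
    "signaling cascade",
    "signalling networks",
    "signalling network",
    "signaling networks",
    "signaling network",
)

#: Pathway-specific verb phrases triggering forward extension.
DEFAULT_VERB_PHRASES = (
    "induced by",
    "regulated by",
    "mediated by",
    "mediated through",
    "activated by",
    "triggered by",
    "stimulated by",
    "suppressed by",
    "inhibited by",
    "driven by",
    "controlled by",
)


@dataclass(frozen=True)
class KeywordSet:
    """Pathway keywords: single tokens plus multi-token combinations.

    Matching is case-insensitive and token-based; at any position the longest
    combination wins and its tokens are not re-matched.  Both British and
    American spellings are included by default.
    """

    base: frozenset[str] = frozenset(_DEFAULT_BASE)
    combinations: tuple[tuple[str, ...], ...] = tuple(
        tuple(phrase.split()) for phrase in _DEFAULT_COMBINATIONS
    )

    def __post_init__(self) -> None:
        for combo in self.combinations:
            if len(combo) < 2:
                raise ValueError(f"combinations need >= 2 tokens, got {combo!r}")

    @classmethod
    def from_lists(
        cls, base: Iterable[str], combinations: Iterable[str]
    ) -> "KeywordSet":
        return cls(
            base=frozenset(w.lower() for w in base),
            combinations=tuple(
                tuple(phrase.lower().split()) for phrase in combinations
            ),
        )


DEFAULT_KEYWORDS = KeywordSet()


@dataclass(frozen=True)
class RuleSegment:
    span: Span
    anchor: Span

    def __post_init__(self) -> None:
        if not self.span.contains(self.anchor):
            raise ValueError("anchor must lie within the segment span")


class GeneRecognizer(Protocol):
    def tag(self, document: Document) -> list[Annotation]: ...


def find_keywords(sentence: Sentence, keywords: Optional[KeywordSet] = None) -> list[Span]:
    """Keyword occurrence spans in a sentence, longest combination first."""
    keywords = keywords or DEFAULT_KEYWORDS
    combos = sorted(keywords.combinations, key=len, reverse=True)
    toks = sentence.tokens
    lowered = [t.text.lower() for t in toks]
    occurrences: list[Span] = []
    i = 0
    while i < len(toks):
        matched = None
        for combo in combos:
            if tuple(lowered[i : i + len(combo)]) == combo:
                matched = len(combo)
                break
        if matched is None and lowered[i] in keywords.base:
            matched = 1
        if matched is None:
            i += 1
        else:
            occurrences.append(Span(toks[i].span.start, toks[i + matched - 1].span.end))
            i += matched
    return occurrences


def _token_range(sentence: Sentence, span: Span) -> tuple[int, int]:
    """Indices [first, last] of tokens inside ``span``."""
    idx = [i for i, t in enumerate(sentence.tokens) if span.contains(t.span)]
    if not idx:
        raise ValueError(f"span [{span.start}, {span.end}) covers no sentence tokens")
    return idx[0], idx[-1]


def backward_extend(
    sentence: Sentence,
    anchor: Span,
    gene_spans: Sequence[Span] = (),
) -> RuleSegment:
    """Extend a keyword anchor leftwards to the nearest stop token.

    Scanning left from the token before the anchor, the segment starts after
    the first token whose class is determiner, separator, preposition /
    subordinating conjunction, wh-word or verb (or at the sentence start).
    Tokens covered by a gene mention in ``gene_spans`` are skipped as atomic
    blocks, so function words inside multi-word protein names ("mammalian
    target of rapamycin") never terminate the scan.
    """
    toks = sentence.tokens
    anchor_first, _ = _token_range(sentence, anchor)
    k = anchor_first - 1
    while k >= 0:
        covering = next((g for g in gene_spans if g.contains(toks[k].span)), None)
        if covering is not None:
            while k >= 0 and covering.contains(toks[k].span):
                k -= 1
            continue
        if token_class(toks[k]) in STOP_CLASSES:
            break
        k -= 1
    start_idx = k + 1
    return RuleSegment(span=Span(toks[start_idx].span.start, anchor.end), anchor=anchor)


def forward_extend(
    sentence: Sentence,
    segment: RuleSegment,
    verb_phrases: Sequence[str] = DEFAULT_VERB_PHRASES,
) -> RuleSegment:
    """Extend a segment rightwards through a pathway verb phrase.

    If the tokens immediately after the anchor begin with one of the listed
    verb phrases, the segment grows through the following tokens up to (but
    excluding) the first punctuation token; otherwise it is unchanged.
    """
    toks = sentence.tokens
    _, anchor_last = _token_range(sentence, segment.anchor)
    after = anchor_last + 1
    lowered = [t.text.lower() for t in toks]
    phrase_tuples = sorted(
        (tuple(p.lower().split()) for p in verb_phrases), key=len, reverse=True
    )
    matched = None
    for phrase in phrase_tuples:
        if tuple(lowered[after : after + len(phrase)]) == phrase:
            matched = len(phrase)
            break
    if matched is None:
        return segment
    end_idx = after + matched - 1
    j = end_idx + 1
    while j < len(toks) and not is_punctuation(toks[j].text):
        end_idx = j
        j += 1
    return RuleSegment(
        span=Span(segment.span.start, toks[end_idx].span.end), anchor=segment.anchor
    )


def apply_rules(
    document: Document,
    keywords: Optional[KeywordSet] = None,
    recognizer: Optional[GeneRecognizer] = None,
    verb_phrases: Sequence[str] = DEFAULT_VERB_PHRASES,
) -> list[Annotation]:
    """Rule annotations: keyword-anchored segments containing a gene mention.

    One annotation per rule segment that fully contains at least one gene
    mention; rule annotations carry neither score nor entry id.  Exact
    duplicate segments (several anchors yielding the same span) collapse to
    one annotation.
    """
    recognizer = recognizer or LexiconGeneRecognizer()
    try:
        gene_annotations = recognizer.tag(document)
    except Exception as exc:
        raise RuleEngineError(
            f"gene recognizer failed on document {document.doc_id!r}: {exc}"
        ) from exc
    annotations: list[Annotation] = []
    seen: set[Span] = set()
    for sentence in document.sentences:
        gene_spans = [
            g.span
            for g in gene_annotations
            if sentence.span.contains(g.span)
        ]
        for anchor in find_keywords(sentence, keywords):
            segment = backward_extend(sentence, anchor, gene_spans)
            segment = forward_extend(sentence, segment, verb_phrases)
            if not any(segment.span.contains(g) for g in gene_spans):
                continue
            if segment.span in seen:
                continue
            seen.add(segment.span)
            annotations.append(
                Annotation(
                    doc_id=document.doc_id,
                    span=segment.span,
                    surface=document.text[segment.span.start : segment.span.end],
                    ann_type="pathway_mention",
                    score=None,
                    source="rule",
                    entry_id=None,
                )
            )
    annotations.sort(key=lambda a: (a.span.start, a.span.end))
    return annotations


def load_gene_lexicon(path: str | Path) -> tuple[str, ...]:
    """Read a plain-text gene lexicon, one symbol or name per line."""
    lines = []
    for line in Path(path).read_text("utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            lines.append(line)
    if not lines:
        raise ValueError(f"gene lexicon {path} is empty")
    return tuple(lines)


_MIXED_RE = re.compile(r"^(?=.*[A-Z])(?=.*\d)[A-Za-z0-9-]{2,}$")


class LexiconGeneRecognizer:
    """Deterministic gene/protein tagger: lexicon matches plus morphology.

    Lexicon entries (possibly multi-word) are matched case-sensitively as
    token sequences, longest first.  In addition, any token mixing upper-case
    letters and digits (length >= 2, not on the stop list) is tagged — this
    catches symbols like "MEK1" that the lexicon misses.
    """

    def __init__(
        self,
        lexicon: Optional[Iterable[str]] = None,
        stoplist: Optional[Iterable[str]] = None,
    ):
        entries = tuple(lexicon) if lexicon is not None else default_gene_lexicon()
        if not entries:
            raise ValueError("gene lexicon must be non-empty")
        self._stop = (
            frozenset(s.lower() for s in stoplist)
            if stoplist is not None
            else default_stopwords()
        )
        self._by_first: dict[str, list[tuple[str, ...]]] = {}
        for name in entries:
            seq = tuple(t.text for t in tokenize(name))
            if not seq:
                continue
            self._by_first.setdefault(seq[0], []).append(seq)
        for seqs in self._by_first.values():
            seqs.sort(key=len, reverse=True)

    def tag(self, document: Document) -> list[Annotation]:
        annotations: list[Annotation] = []
        spans_seen: set[Span] = set()

        def emit(span: Span) -> None:
            if span in spans_seen:
                return
            spans_seen.add(span)
            annotations.append(
                Annotation(
                    doc_id=document.doc_id,
                    span=span,
                    surface=document.text[span.start : span.end],
                    ann_type="gene_mention",
                    score=None,
                    source="rule",
                    entry_id=None,
                )
            )

        for sentence in document.sentences:
            toks = sentence.tokens
            i = 0
            while i < len(toks):
                matched = None
                for seq in self._by_first.get(toks[i].text, ()):
                    if tuple(t.text for t in toks[i : i + len(seq)]) == seq:
                        matched = len(seq)
                        break
                if matched is not None:
                    emit(Span(toks[i].span.start, toks[i + matched - 1].span.end))
                    i += matched
                    continue
                text = toks[i].text
                if (
                    text.lower() not in self._stop
                    and _MIXED_RE.match(text) is not None
                ):
                    emit(toks[i].span)
                i += 1
        annotations.sort(key=lambda a: (a.span.start, a.span.end))
        return annotations


class ImportedAnnotationRecognizer:
    """Gene recognizer backed by externally produced standoff annotations.

    Lets a real CRF-based tagger's output (imported from the native standoff
    TSV) stand in for the bundled lexicon recognizer, e.g. for replication
    runs against the original tool chain.
    """

    def __init__(self, annotations: Iterable[Annotation]):
        self._by_doc: dict[str, list[Annotation]] = {}
        for ann in annotations:
            if ann.ann_type == "gene_mention":
                self._by_doc.setdefault(ann.doc_id, []).append(ann)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ImportedAnnotationRecognizer":
        from .gold_io import read_annotations_tsv

        return cls(read_annotations_tsv(path))

    def tag(self, document: Document) -> list[Annotation]:
        out = []
        for ann in self._by_doc.get(document.doc_id, []):
            if ann.span.end > len(document.text):
                raise ValueError(
                    f"imported gene span [{ann.span.start}, {ann.span.end}) exceeds "
                    f"document {document.doc_id!r} length {len(document.text)}"
                )
            out.append(ann)
        return out
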