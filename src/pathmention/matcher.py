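"""Document-scanning soft dictionary lookup.

The scan works per sentence: every token whose single-token lookup clears the
*lower* SoftTFIDF threshold becomes a candidate start point; from each start
point windows of growing token length are scored against the dictionary, a
run of more than ``miss_limit`` consecutive empty window lengths aborts the
growth, and the longest window whose best match clears the *upper* threshold
is emitted as one dictionary annotation.  Windows never cross sentence
boundaries and exclude sentence-final punctuation; overlapping annotations
from different start points are resolved by score, then length, then leftmost
position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .dictionary import PathwayDictionary
from .metrics import (
    DEFAULT_METRIC_CONFIG,
    MetricConfig,
    TfidfModel,
    _soft_score,
    jaro_winkler,
    tfidf_vector,
)
from .text import is_punctuation
from .types import Annotation, Document, Sentence, Span

__all__ = [
    "MatcherConfig",
    "MatchCandidate",
    "SoftDictionaryMatcher",
    "lookup",
    "find_start_points",
    "scan_document",
    "exact_match_baseline",
]


@dataclass(frozen=True)
class MatcherConfig:
    """Thresholds and window geometry of the document scan.

    ``lower_threshold`` gates start-point detection and window survival,
    ``upper_threshold`` gates emitted matches; ``max_window`` bounds window
    length in tokens (generous relative to the longest dictionary names so
    stop-word insertions still fit); growth stops after more than
    ``miss_limit`` consecutive empty window lengths.
    """

    lower_threshold: float = 0.40
    upper_threshold: float = 0.90
    max_window: int = 25
    miss_limit: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower_threshold <= self.upper_threshold <= 1.0):
            raise ValueError(
                "thresholds must satisfy 0 <= lower <= upper <= 1, got "
                f"{self.lower_threshold}/{self.upper_threshold}"
            )
        if self.max_window < 1:
            raise ValueError("max_window must be >= 1")
        if self.miss_limit < 1:
            raise ValueError("miss_limit must be >= 1")


DEFAULT_MATCHER_CONFIG = MatcherConfig()


@dataclass(frozen=True)
class MatchCandidate:
    start_token: int
    window_len: int
    entry_id: str
    score: float


class SoftDictionaryMatcher:
    """Reusable matcher carrying the dictionary, TFIDF model and caches."""

    def __init__(
        self,
        dictionary: PathwayDictionary,
        model: Optional[TfidfModel] = None,
        metric_cfg: Optional[MetricConfig] = None,
        config: Optional[MatcherConfig] = None,
    ):
        self.dictionary = dictionary
        self.model = model or TfidfModel.from_dictionary(dictionary)
        self.metric_cfg = metric_cfg or DEFAULT_METRIC_CONFIG
        self.config = config or DEFAULT_MATCHER_CONFIG
        self._entry_vectors = {
            e.entry_id: tfidf_vector(e.tokens, self.model) for e in dictionary.entries
        }
        self._vocab = sorted(dictionary.token_index)
        self._close_cache: dict[str, frozenset[str]] = {}
        self._start_cache: dict[str, bool] = {}

    # -- candidate pruning ------------------------------------------------

    def _close_vocab_tokens(self, token: str) -> frozenset[str]:
        """Dictionary vocabulary tokens within the inner JW threshold of ``token``."""
        cached = self._close_cache.get(token)
        if cached is not None:
            return cached
        theta = self.metric_cfg.inner_jw_threshold
        close = {
            v
            for v in self._vocab
            if v == token or jaro_winkler(token, v, self.metric_cfg) >= theta
        }
        result = frozenset(close)
        self._close_cache[token] = result
        return result

    def candidate_entries(self, query_tokens: Sequence[str]) -> set[str]:
        """Entry ids sharing at least one (JW-close) token with the query."""
        ids: set[str] = set()
        for tok in set(query_tokens):
            if self.model.raw_weight(tok, 1) == 0.0:
                continue
            for v in self._close_vocab_tokens(tok):
                ids.update(self.dictionary.token_index[v])
        return ids

    # -- lookup ------------------------------------------------------------

    def lookup(
        self, query_tokens: Sequence[str], threshold: float
    ) -> list[tuple[str, float]]:
        """Entries scoring at least ``threshold`` (and above zero) against the
        query bag, descending by score with ties broken by entry id."""
        vs = tfidf_vector(query_tokens, self.model)
        results = []
        for entry_id in self.candidate_entries(query_tokens):
            score = _soft_score(vs, self._entry_vectors[entry_id], self.metric_cfg)
            if score >= threshold and score > 0.0:
                results.append((entry_id, score))
        results.sort(key=lambda r: (-r[1], r[0]))
        return results

    def is_start_point(self, token_text: str) -> bool:
        tok = token_text.lower()
        cached = self._start_cache.get(tok)
        if cached is None:
            cached = bool(self.lookup([tok], self.config.lower_threshold))
            self._start_cache[tok] = cached
        return cached

    def find_start_points(self, sentence: Sentence) -> list[int]:
        return [
            i
            for i, tok in enumerate(sentence.tokens)
            if self.is_start_point(tok.text)
        ]

    # -- document scan -----------------------------------------------------

    def _scan_sentence(self, doc_id: str, sentence: Sentence) -> list[Annotation]:
        toks = list(sentence.tokens)
        # exclude sentence-final terminators/separators (not closing brackets,
        # which can belong to an acronym-bearing name)
        while toks and toks[-1].text in (".", "!", "?", ";", ":", ","):
            toks.pop()
        if not toks:
            return []
        cfg = self.config
        candidates: list[Annotation] = []
        for i in range(len(toks)):
            if not self.is_start_point(toks[i].text):
                continue
            best: Optional[tuple[int, str, float]] = None  # (win_len, entry, score)
            misses = 0
            max_len = min(cfg.max_window, len(toks) - i)
            for length in range(1, max_len + 1):
                window = [t.text.lower() for t in toks[i : i + length]]
                results = self.lookup(window, cfg.lower_threshold)
                if not results:
                    misses += 1
                    if misses > cfg.miss_limit:
                        break
                    continue
                misses = 0
                entry_id, score = results[0]
                if score >= cfg.upper_threshold:
                    best = (length, entry_id, score)
            if best is None:
                continue
            length, entry_id, score = best
            window_tokens = self._trim_window(toks[i : i + length])
            if not window_tokens:
                continue
            span = Span(window_tokens[0].span.start, window_tokens[-1].span.end)
            candidates.append(
                Annotation(
                    doc_id=doc_id,
                    span=span,
                    surface="",
                    ann_type="pathway_mention",
                    score=score,
                    source="dictionary",
                    entry_id=entry_id,
                )
            )
        return self._resolve_overlaps(candidates)

    def _trim_window(self, tokens: list) -> list:
        """Drop trailing zero-weight stop-word/punctuation tokens.

        A closing ``)`` balancing an opening ``(`` earlier in the window is
        part of the matched name (acronym variants) and is kept.
        """
        stop = self.model.zero_weight_tokens
        toks = list(tokens)
        while toks:
            text = toks[-1].text
            low = text.lower()
            if low in stop:
                toks.pop()
                continue
            if is_punctuation(text):
                if text == ")":
                    earlier = [t.text for t in toks[:-1]]
                    if earlier.count("(") > earlier.count(")"):
                        break
                toks.pop()
                continue
            break
        return toks

    @staticmethod
    def _resolve_overlaps(candidates: list[Annotation]) -> list[Annotation]:
        ordered = sorted(
            candidates,
            key=lambda a: (-(a.score or 0.0), -len(a.span), a.span.start),
        )
        kept: list[Annotation] = []
        for ann in ordered:
            if any(ann.span.overlaps(k.span) for k in kept):
                continue
            kept.append(ann)
        kept.sort(key=lambda a: (a.span.start, a.span.end))
        return kept

    def scan_document(self, document: Document) -> list[Annotation]:
        annotations: list[Annotation] = []
        for sentence in document.sentences:
            for ann in self._scan_sentence(document.doc_id, sentence):
                annotations.append(
                    Annotation(
                        doc_id=ann.doc_id,
                        span=ann.span,
                        surface=document.text[ann.span.start : ann.span.end],
                        ann_type=ann.ann_type,
                        score=ann.score,
                        source=ann.source,
                        entry_id=ann.entry_id,
                    )
                )
        return annotations


# -- module-level conveniences mirroring the matcher methods -----------------


def lookup(
    query_tokens: Sequence[str],
    dictionary: PathwayDictionary,
    model: Optional[TfidfModel] = None,
    threshold: float = 0.40,
    metric_cfg: Optional[MetricConfig] = None,
) -> list[tuple[str, float]]:
    matcher = SoftDictionaryMatcher(dictionary, model=model, metric_cfg=metric_cfg)
    return matcher.lookup([t.lower() for t in query_tokens], threshold)


def find_start_points(
    sentence: Sentence,
    dictionary: PathwayDictionary,
    model: Optional[TfidfModel] = None,
    config: Optional[MatcherConfig] = None,
) -> list[int]:
    matcher = SoftDictionaryMatcher(dictionary, model=model, config=config)
    return matcher.find_start_points(sentence)


def scan_document(
    document: Document,
    dictionary: PathwayDictionary,
    model: Optional[TfidfModel] = None,
    config: Optional[MatcherConfig] = None,
    metric_cfg: Optional[MetricConfig] = None,
) -> list[Annotation]:
    matcher = SoftDictionaryMatcher(
        dictionary, model=model, config=config, metric_cfg=metric_cfg
    )
    return matcher.scan_document(document)


def exact_match_baseline(
    document: Document, dictionary: PathwayDictionary
) -> list[Annotation]:
    """Case-insensitive verbatim dictionary matching, longest-match-wins.

    The baseline that soft matching is designed to improve on: dictionary
    names are matched as exact token sequences only, so stop-word insertions,
    permutations and spelling variants all cause misses.
    """
    by_first: dict[str, list[tuple[tuple[str, ...], str]]] = {}
    for e in dictionary.entries:
        if not e.tokens:
            continue
        by_first.setdefault(e.tokens[0], []).append((e.tokens, e.entry_id))
    for seqs in by_first.values():
        seqs.sort(key=lambda item: (-len(item[0]), item[1]))
    annotations: list[Annotation] = []
    for sentence in document.sentences:
        toks = sentence.tokens
        lowered = [t.text.lower() for t in toks]
        i = 0
        while i < len(toks):
            hit = None
            for seq, entry_id in by_first.get(lowered[i], ()):
                if tuple(lowered[i : i + len(seq)]) == seq:
                    hit = (seq, entry_id)
                    break
            if hit is None:
                i += 1
                continue
            seq, entry_id = hit
            span = Span(toks[i].span.start, toks[i + len(seq) - 1].span.end)
            annotations.append(
                Annotation(
                    doc_id=document.doc_id,
                    span=span,
                    surface=document.text[span.start : span.end],
                    ann_type="pathway_mention",
                    score=1.0,
                    source="dictionary",
                    entry_id=entry_id,
                )
            )
            i += len(seq)
    return annotations
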