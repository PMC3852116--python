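"""Tokenization, sentence splitting and rule-based Penn Treebank POS tagging.

The tokenizer isolates every punctuation character (including ``/``, ``(``,
``)``, ``,``, ``-``) as its own token so that gene symbols inside slash chains
("ras/raf/MAPK") and hyphenated keyword forms ("Wnt-signalling") stay visible
to downstream recognizers.  The POS tagger is a deterministic rule-based
backend behind a pluggable contract: any callable mapping a token sequence to
Penn Treebank tags can replace it.
"""

from __future__ import annotations

import re
from typing import Callable, Iterable, Optional, Sequence

from .types import Document, Sentence, Span, Token

__all__ = [
    "tokenize",
    "split_sentences",
    "pos_tag",
    "token_class",
    "preprocess",
    "RuleBasedTagger",
    "TaggerError",
    "is_punctuation",
    "STOP_CLASSES",
]

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)

#: Punctuation surfaces that count as separators for the rule engine.
_SEPARATOR_TOKENS = frozenset({",", ".", ";", ":"})

STOP_CLASSES = frozenset(
    {"determiner", "separator", "preposition_subconj", "wh_word", "verb"}
)


class TaggerError(RuntimeError):
    """Raised when the configured POS-tagger backend fails or misbehaves."""


def is_punctuation(text: str) -> bool:
    """True for tokens made entirely of non-alphanumeric characters."""
    return bool(text) and not any(ch.isalnum() for ch in text)


def tokenize(text: str, offset: int = 0) -> list[Token]:
    """Split ``text`` into word and single-character punctuation tokens.

    Offsets are relative to the full document when ``offset`` is the position
    of ``text`` within it.  The concatenation of token surfaces with the
    skipped whitespace reconstructs ``text`` exactly.
    """
    return [
        Token(m.group(), Span(m.start() + offset, m.end() + offset))
        for m in _TOKEN_RE.finditer(text)
    ]


def split_sentences(text: str) -> list[Span]:
    """Return sentence spans covering all non-whitespace text.

    A boundary is placed after a run of ``.!?`` that is followed by whitespace
    and then an upper-case letter, digit, quote or opening bracket (or by end
    of text).  This deliberately simple contract splits "Fig. 1 shows X." into
    two sentences; abbreviation-aware splitting is out of scope and the chosen
    behaviour is frozen by the test fixtures.
    """
    if not text.strip():
        return []
    bounds: list[int] = []
    for m in re.finditer(r"[.!?]+", text):
        j = m.end()
        k = j
        while k < len(text) and text[k].isspace():
            k += 1
        if k == len(text):
            bounds.append(j)
        elif k > j and (text[k].isupper() or text[k].isdigit() or text[k] in "(\"'"):
            bounds.append(j)
    spans: list[Span] = []
    prev = 0
    for b in bounds + [len(text)]:
        if b <= prev:
            continue
        seg = text[prev:b]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        if seg.strip():
            spans.append(Span(prev + lead, b - trail))
        prev = b
    return spans


_DETERMINERS = frozenset(
    """the a an this that these those all such some any no each every both
    either neither another""".split()
)
_PREDETERMINERS = frozenset({"half", "quite"})
_PREPOSITIONS = frozenset(
    """of in on at by for with about against between into through during
    before after above below over under from as since until within without
    upon toward towards like per than although while whereas if unless
    because via throughout across along near behind beside despite except
    versus""".split()
)
_WH_WDT = frozenset({"which", "whichever"})
_WH_WP = frozenset({"who", "whom", "what", "whoever", "whomever"})
_WH_WPS = frozenset({"whose"})
_WH_WRB = frozenset({"when", "where", "why", "how", "whatever", "whenever", "wherever"})
_MODALS = frozenset("can could may might must shall should will would".split())
_PRONOUNS = frozenset(
    "he she it they we you i them him her us me his its their our your".split()
)
_CONJUNCTIONS = frozenset({"and", "or", "but", "nor"})

_VERBS_VBZ = frozenset(
    """is has does shows suggests indicates demonstrates reveals activates
    regulates mediates induces triggers involves inhibits blocks promotes
    suppresses enhances modulates controls drives plays remains occurs
    follows requires leads results contributes participates acts binds
    phosphorylates stimulates represses causes appears seems becomes""".split()
)
_VERBS_VBP = frozenset(
    """are have do show suggest indicate demonstrate reveal activate regulate
    mediate induce trigger involve inhibit block promote suppress enhance
    modulate control drive play remain occur follow require lead result
    contribute participate act bind phosphorylate stimulate repress cause
    appear seem become am""".split()
)
_VERBS_VBD = frozenset("was were did had".split())
_VERBS_VB = frozenset({"be"})
_VERBS_VBN = frozenset({"been", "done", "shown", "given", "taken", "known", "seen", "found"})

_ING_NOUNS = frozenset(
    """signalling signaling thing something anything everything nothing
    string spring ring king wing during morning evening offspring""".split()
)


class RuleBasedTagger:
    """Deterministic lexicon + suffix tagger emitting Penn Treebank tags.

    Coverage is tuned for the token classes the rule engine depends on
    (determiners, prepositions, wh-words, verbs, separators); everything else
    defaults to a noun tag, which is harmless for rule anchoring.
    """

    def tag(self, tokens: Sequence[str]) -> list[str]:
        tags: list[str] = []
        for tok in tokens:
            tags.append(self._tag_one(tok))
        return tags

    @staticmethod
    def _tag_one(tok: str) -> str:
        if is_punctuation(tok):
            if tok in (".", ","):
                return tok
            if tok in (";", ":"):
                return ":"
            return "SYM"
        low = tok.lower()
        if re.fullmatch(r"\d+(\.\d+)?", tok):
            return "CD"
        if low in _DETERMINERS:
            return "DT"
        if low in _PREDETERMINERS:
            return "PDT"
        if low in _WH_WDT:
            return "WDT"
        if low in _WH_WP:
            return "WP"
        if low in _WH_WPS:
            return "WP$"
        if low in _WH_WRB:
            return "WRB"
        if low in _PREPOSITIONS:
            return "IN"
        if low in _MODALS:
            return "MD"
        if low in _PRONOUNS:
            return "PRP"
        if low in _CONJUNCTIONS:
            return "CC"
        if low in _VERBS_VBZ:
            return "VBZ"
        if low in _VERBS_VBP:
            return "VBP"
        if low in _VERBS_VBD:
            return "VBD"
        if low in _VERBS_VB:
            return "VB"
        if low in _VERBS_VBN:
            return "VBN"
        if low.endswith("ed") and len(low) > 3:
            return "VBD"
        if low.endswith("ing") and len(low) > 4 and low not in _ING_NOUNS:
            return "VBG"
        if tok[0].isupper() and len(tok) > 1 and tok[1:].islower():
            return "NNP"
        return "NN"


_DEFAULT_TAGGER = RuleBasedTagger()

TaggerBackend = Callable[[Sequence[str]], Sequence[str]]


def pos_tag(sentence: Sentence, tagger: Optional[TaggerBackend] = None) -> Sentence:
    """Return a copy of ``sentence`` with every token POS-tagged."""
    backend = tagger if tagger is not None else _DEFAULT_TAGGER.tag
    surfaces = [t.text for t in sentence.tokens]
    try:
        tags = list(backend(surfaces))
    except Exception as exc:  # pragma: no cover - backend failure path
        raise TaggerError(f"POS tagger backend failed: {exc}") from exc
    if len(tags) != len(surfaces) or any(not t for t in tags):
        raise TaggerError(
            f"POS tagger returned {len(tags)} tags for {len(surfaces)} tokens"
        )
    tokens = tuple(tok.with_pos(tag) for tok, tag in zip(sentence.tokens, tags))
    return Sentence(span=sentence.span, tokens=tokens)


def token_class(token: Token) -> str:
    """Map a tagged token to one of the rule engine's stop-token classes.

    Classes: ``determiner`` (DT/PDT), ``separator`` (comma, period, semicolon,
    colon), ``preposition_subconj`` (IN), ``wh_word`` (WDT/WP/WP$/WRB),
    ``verb`` (any VB* tag) and ``other``.  Total: every tagged token maps to
    exactly one class.
    """
    if token.text in _SEPARATOR_TOKENS:
        return "separator"
    pos = token.pos or ""
    if pos in ("DT", "PDT"):
        return "determiner"
    if pos == "IN":
        return "preposition_subconj"
    if pos in ("WDT", "WP", "WP$", "WRB"):
        return "wh_word"
    if pos.startswith("VB"):
        return "verb"
    return "other"


def preprocess(
    text: str, doc_id: str = "doc", tagger: Optional[TaggerBackend] = None
) -> Document:
    """Full preprocessing: sentence split, tokenize, POS-tag."""
    sentences = []
    for span in split_sentences(text):
        tokens = tuple(tokenize(text[span.start : span.end], offset=span.start))
        sent = Sentence(span=span, tokens=tokens)
        sentences.append(pos_tag(sent, tagger))
    return Document(doc_id=doc_id, text=text, sentences=tuple(sentences))
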