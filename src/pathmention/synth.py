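"""Synthetic evaluation corpora with controlled pathway-name variation.

The generator embeds dictionary names into carrier sentences and applies the
variation typology that soft matching is meant to absorb: stop-word insertion
and deletion, preposition-driven word permutation ("p53 signalling pathway"
-> "signalling pathway of p53"), keyword alternation ("MAPK pathway" vs
"MAPK signalling pathway") and British/American spelling swaps.  Distractor
sentences contain a pathway keyword in a non-biological reading ("the
diagnostic pathway") and no gene mention, exercising the precision side.
Rule-only sentences embed invented keyword + gene mentions that are absent
from the dictionary, exercising the complementarity of the two components.

Generation is a pure function of (dictionary, config, seed): the same inputs
produce byte-identical corpora.  Carrier templates place only stop-words and
punctuation after the embedded mention so that gold spans are recoverable
exactly; gene-bearing and gene-free templates are both included so the
gene-containment gate of the rule engine can be exercised independently.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .dictionary import PathwayDictionary
from .resources import default_stopwords
from .text import tokenize
from .types import Annotation, Span

__all__ = ["PerturbationConfig", "SyntheticCorpus", "generate_synthetic_corpus"]


@dataclass(frozen=True)
class PerturbationConfig:
    """Per-sentence perturbation probabilities and the generation seed."""

    p_stopword_insert: float = 0.0
    p_stopword_delete: float = 0.0
    p_permute: float = 0.0
    p_keyword_swap: float = 0.0
    p_spelling_swap: float = 0.0
    distractor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_stopword_insert",
            "p_stopword_delete",
            "p_permute",
            "p_keyword_swap",
            "p_spelling_swap",
            "distractor_rate",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class SyntheticCorpus:
    texts: dict[str, str]
    gold: list[Annotation]
    manifest: list[dict]


# Carrier templates: (prefix, suffix, carries_gene).  Suffixes contain only
# stop-words and punctuation so dictionary matches cannot legitimately extend
# past the gold span.
_TEMPLATES: tuple[tuple[str, str, bool], ...] = (
    ("Earlier work established that {gene} acts upstream of the ", ".", True),
    ("We confirmed that loss of {gene} attenuated the ", ".", True),
    ("Immunoblotting linked {gene} to the ", ".", True),
    ("The ", " was also among these.", False),
    ("Several reports implicate {gene} in the ", ".", True),
    ("Treatment abolished the ", " in all of them.", False),
)

# Carrier gene symbols are chosen to have no Jaro-Winkler-close token in the
# demo dictionary vocabulary, so a gene adjacent to an embedded name cannot
# glue onto the mention's match window.
_CARRIER_GENES = ("BRCA1", "CDK2", "SMAD4", "PTEN", "GRB2", "SHC1", "IRS1", "NFKB1")

# Rule-only mentions: gene symbol + filler adjectives/nouns absent from the
# demo dictionary + a pathway keyword tail.  The filler deliberately avoids
# -ed forms, which the POS tagger reads as verbs (rule stop tokens).
_RULE_ONLY_GENES = ("GRIN2B", "KCNQ3", "SLC7A11", "RAB11A", "DDX3X", "USP9X", "TRPM3")
_RULE_ONLY_SHAPES = (
    "{gene} driven relay cascade",
    "{gene} specific relay cascade",
    "{gene} intrinsic relay network",
)
_RULE_ONLY_TEMPLATES = (
    ("Staining confirmed that the ", " was intact."),
    ("Histology suggested that the ", " was not involved."),
)

_DISTRACTORS = (
    "The diagnostic pathway was followed without delay.",
    "The referral pathway was also among these.",
    "A formal review cascade was agreed by the panel.",
    "Staff discussed the escalation pathway at length.",
    "The screening pathway was under review.",
)

_BASE_KEYWORDS = frozenset(
    "pathway pathways signalling signaling transduction cascade cascades "
    "network networks".split()
)
_SWAPPABLE_TAILS = frozenset(
    "pathway pathways cascade cascades network networks".split()
)


def _name_words(name: str) -> list[str]:
    return [t.text for t in tokenize(name)]


def _is_plain(words: Sequence[str]) -> bool:
    return all(any(ch.isalnum() for ch in w) for w in words) and len(words) >= 2


def _eligible(words: list[str], kind: str, stopwords: frozenset[str]) -> bool:
    if not _is_plain(words):
        return False
    lowered = [w.lower() for w in words]
    if kind == "stopword_insert":
        return True
    if kind == "stopword_delete":
        return any(w in stopwords for w in lowered)
    if kind == "permute":
        tail = _keyword_tail(lowered)
        return 0 < tail < len(words)
    if kind == "keyword_swap":
        return lowered[-1] in _SWAPPABLE_TAILS
    if kind == "spelling_swap":
        return any(w in ("signalling", "signaling") for w in lowered)
    raise ValueError(kind)


def _keyword_tail(lowered: Sequence[str]) -> int:
    n = 0
    for w in reversed(lowered):
        if w in _BASE_KEYWORDS:
            n += 1
        else:
            break
    return n


def _perturb(words: list[str], kind: str, rng: random.Random, stopwords) -> list[str]:
    lowered = [w.lower() for w in words]
    if kind == "stopword_insert":
        pos = rng.randrange(1, len(words))
        return words[:pos] + [rng.choice(("the", "of", "a"))] + words[pos:]
    if kind == "stopword_delete":
        idx = [i for i, w in enumerate(lowered) if w in stopwords]
        drop = rng.choice(idx)
        return words[:drop] + words[drop + 1 :]
    if kind == "permute":
        tail = _keyword_tail(lowered)
        return words[-tail:] + ["of"] + words[:-tail]
    if kind == "keyword_swap":
        if len(words) >= 2 and lowered[-2] in ("signalling", "signaling"):
            return words[:-2] + words[-1:]
        return words[:-1] + ["signalling", words[-1]]
    if kind == "spelling_swap":
        swap = {"signalling": "signaling", "signaling": "signalling"}
        return [swap.get(w.lower(), w) for w in words]
    raise ValueError(kind)


_PERTURBATION_ORDER = (
    ("stopword_insert", "p_stopword_insert"),
    ("stopword_delete", "p_stopword_delete"),
    ("permute", "p_permute"),
    ("keyword_swap", "p_keyword_swap"),
    ("spelling_swap", "p_spelling_swap"),
)


def generate_synthetic_corpus(
    dictionary: PathwayDictionary,
    n_sentences: int,
    cfg: PerturbationConfig,
    rule_only_fraction: float = 0.0,
    sentences_per_doc: int = 5,
    entry_ids: Optional[Sequence[str]] = None,
    sample: str = "random",
) -> SyntheticCorpus:
    """Generate carrier sentences with exactly-known gold spans.

    ``entry_ids`` restricts the dictionary names drawn from; ``sample`` is
    ``random`` (names drawn with replacement) or ``distinct`` (each name used
    at most once, requiring ``n_sentences`` <= pool size).  The manifest
    records, per sentence, the kind (dict_mention / rule_only / distractor),
    the perturbation applied and the embedded mention.
    """
    if dictionary.n_entries == 0:
        raise ValueError("dictionary must be non-empty")
    if n_sentences < 1:
        raise ValueError("n_sentences must be >= 1")
    if not (0.0 <= rule_only_fraction <= 1.0):
        raise ValueError("rule_only_fraction must lie in [0, 1]")
    stopwords = default_stopwords()
    rng = random.Random(cfg.seed)
    pool = [
        e
        for e in dictionary.entries
        if entry_ids is None or e.entry_id in set(entry_ids)
    ]
    if not pool:
        raise ValueError("entry_ids selected no dictionary entries")
    if sample == "distinct":
        if n_sentences > len(pool):
            raise ValueError(
                f"distinct sampling needs n_sentences <= {len(pool)} entries"
            )
        order = list(pool)
        rng.shuffle(order)
        distinct_iter = iter(order)
    elif sample != "random":
        raise ValueError("sample must be 'random' or 'distinct'")

    texts: dict[str, str] = {}
    gold: list[Annotation] = []
    manifest: list[dict] = []
    doc_sentences: list[str] = []
    doc_gold: list[tuple[int, int, str, Optional[str]]] = []  # offsets in doc
    doc_index = 0

    def flush_doc() -> None:
        nonlocal doc_sentences, doc_gold, doc_index
        if not doc_sentences:
            return
        doc_id = f"synth-{doc_index:04d}"
        text = " ".join(doc_sentences)
        texts[doc_id] = text
        for start, end, mention, entry_id in doc_gold:
            gold.append(
                Annotation(
                    doc_id=doc_id,
                    span=Span(start, end),
                    surface=text[start:end],
                    ann_type="pathway_mention",
                    score=None,
                    source="gold",
                    entry_id=entry_id,
                )
            )
        doc_index += 1
        doc_sentences = []
        doc_gold = []

    def pick_entry(kind: Optional[str]):
        if sample == "distinct":
            return next(distinct_iter)
        if kind is None:
            return rng.choice(pool)
        eligible = [e for e in pool if _eligible(_name_words(e.name), kind, stopwords)]
        if not eligible:
            raise ValueError(f"no dictionary entry eligible for perturbation {kind!r}")
        return rng.choice(eligible)

    for i in range(n_sentences):
        offset = sum(len(s) + 1 for s in doc_sentences)  # +1 for joining space
        kind_roll = rng.random()
        if kind_roll < cfg.distractor_rate:
            sentence = rng.choice(_DISTRACTORS)
            doc_sentences.append(sentence)
            manifest.append(
                {"sentence": i, "kind": "distractor", "perturbation": "", "mention": ""}
            )
        elif rng.random() < rule_only_fraction:
            gene = rng.choice(_RULE_ONLY_GENES)
            mention = rng.choice(_RULE_ONLY_SHAPES).format(gene=gene)
            prefix, suffix = rng.choice(_RULE_ONLY_TEMPLATES)
            sentence = prefix + mention + suffix
            start = offset + len(prefix)
            doc_sentences.append(sentence)
            doc_gold.append((start, start + len(mention), mention, None))
            manifest.append(
                {
                    "sentence": i,
                    "kind": "rule_only",
                    "perturbation": "",
                    "mention": mention,
                }
            )
        else:
            perturbation = ""
            for kind, attr in _PERTURBATION_ORDER:
                if rng.random() < getattr(cfg, attr):
                    perturbation = kind
                    break
            entry = pick_entry(perturbation or None)
            words = _name_words(entry.name)
            if perturbation and _eligible(words, perturbation, stopwords):
                mention = " ".join(_perturb(words, perturbation, rng, stopwords))
            else:
                perturbation = ""  # no perturbation drawn, or entry not eligible
                mention = entry.name
            prefix, suffix, has_gene = rng.choice(_TEMPLATES)
            prefix = prefix.format(gene=rng.choice(_CARRIER_GENES))
            sentence = prefix + mention + suffix
            start = offset + len(prefix)
            doc_sentences.append(sentence)
            doc_gold.append((start, start + len(mention), mention, entry.entry_id))
            manifest.append(
                {
                    "sentence": i,
                    "kind": "dict_mention",
                    "perturbation": perturbation,
                    "mention": mention,
                    "entry_id": entry.entry_id,
                }
            )
        if len(doc_sentences) >= sentences_per_doc:
            flush_doc()
    flush_doc()
    return SyntheticCorpus(texts=texts, gold=gold, manifest=manifest)
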