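"""End-to-end tagging: preprocess, soft-match, apply rules, merge."""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .dictionary import PathwayDictionary
from .evaluate import merge
from .matcher import MatcherConfig, SoftDictionaryMatcher, exact_match_baseline
from .metrics import MetricConfig
from .rules import (
    DEFAULT_VERB_PHRASES,
    GeneRecognizer,
    KeywordSet,
    LexiconGeneRecognizer,
    apply_rules,
)
from .text import preprocess
from .types import Annotation, Document

__all__ = ["PathwayTagger"]


class PathwayTagger:
    """The full recognizer: soft dictionary matching + rules + merging.

    Components can be run separately (``tag_dictionary``, ``tag_rules``,
    ``tag_baseline``) or combined (``tag``, which merges the first two).
    """

    def __init__(
        self,
        dictionary: PathwayDictionary,
        matcher_config: Optional[MatcherConfig] = None,
        metric_config: Optional[MetricConfig] = None,
        keywords: Optional[KeywordSet] = None,
        recognizer: Optional[GeneRecognizer] = None,
        verb_phrases: Sequence[str] = DEFAULT_VERB_PHRASES,
    ):
        self.dictionary = dictionary
        self.matcher = SoftDictionaryMatcher(
            dictionary, metric_cfg=metric_config, config=matcher_config
        )
        self.keywords = keywords or KeywordSet()
        self.recognizer = recognizer or LexiconGeneRecognizer()
        self.verb_phrases = tuple(verb_phrases)

    def prepare(self, text: str, doc_id: str = "doc") -> Document:
        return preprocess(text, doc_id=doc_id)

    def tag_dictionary(self, document: Document) -> list[Annotation]:
        return self.matcher.scan_document(document)

    def tag_rules(self, document: Document) -> list[Annotation]:
        return apply_rules(
            document,
            keywords=self.keywords,
            recognizer=self.recognizer,
            verb_phrases=self.verb_phrases,
        )

    def tag_baseline(self, document: Document) -> list[Annotation]:
        return exact_match_baseline(document, self.dictionary)

    def tag(self, document: Document) -> list[Annotation]:
        return merge(
            self.tag_dictionary(document),
            self.tag_rules(document),
            text=document.text,
        )

    def tag_corpus(
        self, texts: dict[str, str], component: str = "merged"
    ) -> list[Annotation]:
        """Tag every document of a corpus with one component.

        ``component`` is one of ``dictionary``, ``rules``, ``baseline`` or
        ``merged``.
        """
        taggers = {
            "dictionary": self.tag_dictionary,
            "rules": self.tag_rules,
            "baseline": self.tag_baseline,
            "merged": self.tag,
        }
        if component not in taggers:
            raise ValueError(
                f"unknown component {component!r}; choose from {sorted(taggers)}"
            )
        out: list[Annotation] = []
        for doc_id in sorted(texts):
            document = self.prepare(texts[doc_id], doc_id=doc_id)
            out.extend(taggers[component](document))
        return out
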