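"""Keyword anchoring, backward/forward extension and the gene gate."""

import pytest

from pathmention.rules import (
    DEFAULT_VERB_PHRASES,
    ImportedAnnotationRecognizer,
    KeywordSet,
    LexiconGeneRecognizer,
    RuleEngineError,
    apply_rules,
    backward_extend,
    find_keywords,
    forward_extend,
)
from pathmention.text import preprocess
from pathmention.types import Annotation, Span


def sent(text):
    return preprocess(text).sentences[0], text


def surfaces(spans, text):
    return [text[s.start : s.end] for s in spans]


class TestKeywords:
    def test_combination_wins_over_base(self):
        s, text = sent("the MAPK signalling pathway")
        assert surfaces(find_keywords(s), text) == ["signalling pathway"]

    def test_base_keyword_alone(self):
        s, text = sent("a gene regulatory network")
        assert surfaces(find_keywords(s), text) == ["network"]

    def test_no_keywords(self):
        s, _ = sent("no relevant words here")
        assert find_keywords(s) == []

    def test_plural_combination_single_anchor(self):
        s, text = sent("the MEK and ERK signalling pathways")
        assert surfaces(find_keywords(s), text) == ["signalling pathways"]

    def test_consumed_tokens_not_rematched(self):
        s, text = sent("signal transduction pathway analysis")
        assert surfaces(find_keywords(s), text) == ["signal transduction pathway"]

    def test_combinations_must_be_multi_token(self):
        with pytest.raises(ValueError):
            KeywordSet(combinations=(("pathway",),))


class TestBackward:
    def anchor(self, s, text, phrase):
        start = text.index(phrase)
        return Span(start, start + len(phrase))

    def test_stops_at_determiner(self):
        s, text = sent("Activation of the p53 signalling pathway")
        seg = backward_extend(s, self.anchor(s, text, "signalling pathway"))
        assert text[seg.span.start : seg.span.end] == "p53 signalling pathway"

    def test_anchor_at_sentence_start(self):
        s, text = sent("pathway analysis was performed")
        seg = backward_extend(s, self.anchor(s, text, "pathway"))
        assert text[seg.span.start : seg.span.end] == "pathway"

    def test_stops_at_verb(self):
        s, text = sent("cells activate the Wnt cascade")
        seg = backward_extend(s, self.anchor(s, text, "cascade"))
        assert text[seg.span.start : seg.span.end] == "Wnt cascade"

    def test_gene_spans_are_atomic(self):
        text = "Inhibition of the mammalian target of rapamycin signalling pathway"
        s, _ = sent(text)
        anchor = self.anchor(s, text, "signalling pathway")
        gene_start = text.index("mammalian")
        gene = Span(gene_start, gene_start + len("mammalian target of rapamycin"))
        # without gene info the inner "of" stops the scan ...
        seg_plain = backward_extend(s, anchor)
        assert text[seg_plain.span.start : seg_plain.span.end] == (
            "rapamycin signalling pathway"
        )
        # ... with the gene span treated as a block the scan reaches "the"
        seg = backward_extend(s, anchor, gene_spans=[gene])
        assert text[seg.span.start : seg.span.end] == (
            "mammalian target of rapamycin signalling pathway"
        )


class TestForward:
    def test_verb_phrase_extension_stops_at_punctuation(self):
        text = "the pathway regulated by MDM2, however, was silent"
        s, _ = sent(text)
        start = text.index("pathway")
        anchor = Span(start, start + len("pathway"))
        seg = backward_extend(s, anchor)
        seg = forward_extend(s, seg, DEFAULT_VERB_PHRASES)
        assert text[seg.span.start : seg.span.end] == "pathway regulated by MDM2"

    def test_immediate_punctuation_leaves_segment_unchanged(self):
        text = "they mapped the pathway."
        s, _ = sent(text)
        start = text.index("pathway")
        seg = backward_extend(s, Span(start, start + len("pathway")))
        assert forward_extend(s, seg) == seg

    def test_unlisted_phrase_leaves_segment_unchanged(self):
        text = "the pathway that we studied"
        s, _ = sent(text)
        start = text.index("pathway")
        seg = backward_extend(s, Span(start, start + len("pathway")))
        assert forward_extend(s, seg) == seg


class TestApplyRules:
    def test_complex_coordinated_mention_single_annotation(self):
        text = (
            "These results demonstrated activation of the ras/raf/MAPK kinase "
            "(MEK)/ERK and phosphatidylinositol 3-kinase (PI-3K)/AKT/mammalian "
            "target of rapamycin (mTOR) signalling pathways."
        )
        doc = preprocess(text)
        anns = apply_rules(doc)
        assert len(anns) == 1
        assert anns[0].surface.startswith("ras/raf/MAPK")
        assert anns[0].surface.endswith("signalling pathways")

    def test_keyword_without_gene_rejected(self):
        doc = preprocess("Consequently, the diagnostic pathway was followed.")
        assert apply_rules(doc) == []

    def test_no_keyword_no_annotation(self):
        doc = preprocess("In these mice, microglial activation occurred early.")
        assert apply_rules(doc) == []

    def test_gating_property_no_genes_no_annotations(self):
        doc = preprocess("Activation of the p53 signalling pathway was measured.")
        assert apply_rules(doc)  # sanity: gene present -> annotation
        empty_recognizer = ImportedAnnotationRecognizer([])
        assert apply_rules(doc, recognizer=empty_recognizer) == []

    def test_every_annotation_contains_gene_and_keyword(self, demo_tagger):
        text = (
            "BRCA1 loss activated the p53 signalling pathway. "
            "We watched the Wnt cascade triggered by GSK3B, then waited. "
            "The referral pathway was also among these."
        )
        doc = preprocess(text)
        recognizer = LexiconGeneRecognizer()
        genes = recognizer.tag(doc)
        anns = apply_rules(doc, recognizer=recognizer)
        assert anns, "expected at least one rule annotation"
        for ann in anns:
            assert any(ann.span.contains(g.span) for g in genes)
            covering = [
                s for s in doc.sentences if s.span.contains(ann.span)
            ]
            assert covering, "rule annotations never cross sentence boundaries"
            assert find_keywords(covering[0])

    def test_recognizer_failure_wrapped(self):
        class Broken:
            def tag(self, document):
                raise OSError("backend gone")

        doc = preprocess("the p53 pathway")
        with pytest.raises(RuleEngineError, match="backend gone"):
            apply_rules(doc, recognizer=Broken())


class TestLexiconRecognizer:
    def test_lexicon_symbol_tagged(self):
        doc = preprocess("p53 was induced.")
        recognizer = LexiconGeneRecognizer(["p53"])
        assert [a.surface for a in recognizer.tag(doc)] == ["p53"]

    def test_morphology_heuristic(self):
        doc = preprocess("MEK1 was absent from the list.")
        recognizer = LexiconGeneRecognizer(["p53"])
        assert [a.surface for a in recognizer.tag(doc)] == ["MEK1"]

    def test_stopwords_never_genes(self):
        doc = preprocess("The result was THE1 only.")
        recognizer = LexiconGeneRecognizer(["p53"], stoplist=["the", "the1", "only"])
        assert recognizer.tag(doc) == []

    def test_multiword_lexicon_entry(self):
        doc = preprocess("Binding of mammalian target of rapamycin was strong.")
        recognizer = LexiconGeneRecognizer(["mammalian target of rapamycin"])
        (ann,) = recognizer.tag(doc)
        assert ann.surface == "mammalian target of rapamycin"

    def test_case_sensitive_lexicon(self):
        doc = preprocess("RAS differs from ras in casing.")
        recognizer = LexiconGeneRecognizer(["ras"])
        assert [a.surface for a in recognizer.tag(doc)] == ["ras"]

    def test_imported_annotations_validated(self):
        doc = preprocess("short text")
        bad = Annotation(
            doc_id="doc",
            span=Span(0, 500),
            surface="",
            ann_type="gene_mention",
            source="gold",
        )
        recognizer = ImportedAnnotationRecognizer([bad])
        with pytest.raises(ValueError, match="exceeds"):
            recognizer.tag(doc)
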