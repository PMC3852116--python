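"""Soft dictionary scanning: start points, windows, thresholds, baseline."""

import pytest

from pathmention.matcher import (
    MatcherConfig,
    SoftDictionaryMatcher,
    exact_match_baseline,
)
from pathmention.metrics import softtfidf
from pathmention.text import preprocess
from pathmention.types import Span

from conftest import build_dictionary


@pytest.fixture()
def matcher(toy_dictionary):
    return SoftDictionaryMatcher(toy_dictionary)


class TestLookup:
    def test_entry_self_match_ranks_first_with_score_one(self, matcher):
        results = matcher.lookup(["p53", "signalling", "pathway"], threshold=0.9)
        assert results[0] == ("TOY:1", 1.0)

    def test_no_shared_tokens_gives_empty_result(self, matcher):
        assert matcher.lookup(["unrelated", "tokens"], threshold=0.4) == []

    def test_pruned_lookup_equals_brute_force(self, matcher, toy_dictionary):
        """Index-pruned lookup must equal scoring every entry directly."""
        queries = [
            ["p53", "pathway"],
            ["signalling", "pathway", "of", "p53"],
            ["the", "wnt", "signaling", "cascade"],
            ["rna", "degradation"],
            ["oxidative", "stress"],
            ["mapkk", "signaling"],
        ]
        for query in queries:
            brute = []
            for entry in toy_dictionary.entries:
                score = softtfidf(query, list(entry.tokens), matcher.model)
                if score >= 0.4 and score > 0:
                    brute.append((entry.entry_id, score))
            brute.sort(key=lambda r: (-r[1], r[0]))
            assert matcher.lookup(query, threshold=0.4) == brute

    def test_ranked_descending(self, matcher):
        results = matcher.lookup(["signalling", "pathway"], threshold=0.0)
        scores = [s for _, s in results]
        assert scores == sorted(scores, reverse=True)


class TestStartPoints:
    def test_start_points_follow_single_token_lookup(self, matcher):
        doc = preprocess("The MAPK signalling pathway is active")
        sent = doc.sentences[0]
        idx = set(matcher.find_start_points(sent))
        for i, tok in enumerate(sent.tokens):
            expected = bool(matcher.lookup([tok.text.lower()], matcher.config.lower_threshold))
            assert (i in idx) == expected
        starts = {sent.tokens[i].text for i in idx}
        # discriminative name tokens anchor; stop-words never do
        assert {"MAPK", "pathway"} <= starts
        assert "The" not in starts and "is" not in starts

    def test_stopword_only_sentence_has_none(self, matcher):
        doc = preprocess("And then it was all of them again")
        assert matcher.find_start_points(doc.sentences[0]) == []

    def test_punctuation_never_a_start_point(self, matcher):
        doc = preprocess("/ ( ) , . ;")
        assert matcher.find_start_points(doc.sentences[0]) == []


class TestScan:
    def test_verbatim_name_exact_span_and_unit_score(self, matcher):
        text = "Our data support a role for the MAPK signalling pathway in this process."
        doc = preprocess(text)
        (ann,) = matcher.scan_document(doc)
        assert ann.surface == "MAPK signalling pathway"
        assert ann.score == 1.0
        assert ann.entry_id == "TOY:2"

    def test_permuted_name_recovered(self, matcher, demo_tagger):
        text = "Treatment engaged the signalling pathway of p53 here."
        # toy dictionary: the permuted form is matched (span depends on which
        # tokens can anchor a window under the toy statistics)
        doc = preprocess(text)
        (ann,) = matcher.scan_document(doc)
        assert ann.score >= 0.9
        assert ann.entry_id == "TOY:1"
        assert ann.span.overlaps(Span(text.index("signalling"), text.index("p53") + 3))
        # full-size dictionary: the whole permuted mention is recovered
        (demo_ann,) = demo_tagger.tag_dictionary(demo_tagger.prepare(text))
        assert demo_ann.surface == "signalling pathway of p53"
        assert demo_ann.score == 1.0

    def test_ambiguous_keyword_alone_not_matched(self, matcher):
        doc = preprocess("Consequently, the diagnostic pathway was followed.")
        assert matcher.scan_document(doc) == []

    def test_all_scores_above_upper_threshold(self, matcher, toy_dictionary):
        doc = preprocess(
            "They probed the Wnt signalling cascade. RNA degradation was induced. "
            "We saw the signalling pathway of p53 too."
        )
        anns = matcher.scan_document(doc)
        assert len(anns) == 3
        for ann in anns:
            assert ann.score >= matcher.config.upper_threshold

    def test_raising_upper_threshold_never_adds_annotations(self, toy_dictionary):
        doc = preprocess(
            "We saw the signaling pathway of p53 and also the Wnt signaling cascade."
        )
        counts = []
        for upper in (0.90, 0.95, 0.999):
            m = SoftDictionaryMatcher(
                toy_dictionary, config=MatcherConfig(upper_threshold=upper)
            )
            counts.append(len(m.scan_document(doc)))
        assert counts == sorted(counts, reverse=True)

    def test_output_spans_superset_of_baseline(self, demo_tagger, demo_dictionary):
        from pathmention.synth import PerturbationConfig, generate_synthetic_corpus

        corpus = generate_synthetic_corpus(
            demo_dictionary, 40, PerturbationConfig(seed=99)
        )
        for doc_id, text in corpus.texts.items():
            doc = demo_tagger.prepare(text, doc_id=doc_id)
            soft_spans = {a.span for a in demo_tagger.tag_dictionary(doc)}
            base_spans = {a.span for a in demo_tagger.tag_baseline(doc)}
            assert base_spans <= soft_spans

    def test_annotations_within_window_budget(self, matcher):
        doc = preprocess("the p53 signalling pathway acts via the Wnt signalling cascade.")
        for ann in matcher.scan_document(doc):
            assert len(ann.surface.split()) <= matcher.config.max_window


class TestBaseline:
    def test_verbatim_match(self, toy_dictionary):
        doc = preprocess("We studied the MAPK signalling pathway in cells.")
        (ann,) = exact_match_baseline(doc, toy_dictionary)
        assert ann.surface == "MAPK signalling pathway"

    def test_permutation_not_matched(self, toy_dictionary):
        doc = preprocess("We studied the signalling pathway of p53 in cells.")
        assert exact_match_baseline(doc, toy_dictionary) == []

    def test_longest_match_wins(self):
        d = build_dictionary(
            {"A:1": "MAPK signalling", "A:2": "MAPK signalling pathway"}
        )
        doc = preprocess("the MAPK signalling pathway was seen")
        (ann,) = exact_match_baseline(doc, d)
        assert ann.entry_id == "A:2"
        assert ann.surface == "MAPK signalling pathway"

    def test_case_insensitive(self, toy_dictionary):
        doc = preprocess("RNA DEGRADATION was measured.")
        (ann,) = exact_match_baseline(doc, toy_dictionary)
        assert ann.entry_id == "TOY:4"
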