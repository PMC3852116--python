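"""Merging algebra and strict/lenient scoring."""

import random

import pytest

from pathmention.evaluate import (
    EvaluationCounts,
    aggregate_mentions,
    compute_prf,
    match_annotations,
    merge,
)
from pathmention.types import Annotation, Span


def ann(start, end, source="dictionary", doc_id="d1", score=1.0, entry_id=None):
    if source in ("rule", "gold"):
        score = None
    return Annotation(
        doc_id=doc_id,
        span=Span(start, end),
        surface="",
        ann_type="pathway_mention",
        score=score,
        source=source,
        entry_id=entry_id,
    )


class TestMerge:
    def test_disjoint_sets_concatenate_in_offset_order(self):
        out = merge([ann(20, 30)], [ann(0, 10, "rule")])
        assert [(a.span.start, a.span.end, a.source) for a in out] == [
            (0, 10, "rule"),
            (20, 30, "dictionary"),
        ]

    def test_overlap_produces_covering_annotation(self):
        out = merge([ann(10, 25, score=0.95)], [ann(18, 40, "rule")])
        (m,) = out
        assert (m.span.start, m.span.end) == (10, 40)
        assert m.source == "merged"
        assert m.score == 0.95

    def test_transitive_chain_collapses_to_one(self):
        out = merge([ann(0, 10), ann(18, 30)], [ann(8, 20, "rule")])
        (m,) = out
        assert (m.span.start, m.span.end) == (0, 30)

    def test_entry_id_kept_only_when_unambiguous(self):
        out = merge([ann(0, 10, entry_id="K:1")], [ann(5, 15, "rule")])
        assert out[0].entry_id == "K:1"
        out = merge([ann(0, 10, entry_id="K:1"), ann(12, 20, entry_id="K:2")], [ann(5, 15, "rule")])
        assert out[0].entry_id is None

    def test_cross_document_mixture_rejected(self):
        with pytest.raises(ValueError):
            merge([ann(0, 10, doc_id="a")], [ann(0, 10, "rule", doc_id="b")])

    def test_surface_recovered_from_text(self):
        text = "abcdefghij"
        out = merge([ann(0, 4)], [ann(2, 8, "rule")], text=text)
        assert out[0].surface == "abcdefgh"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotent_and_non_overlapping(self, seed):
        rng = random.Random(seed)
        dict_anns = [
            ann(s, s + rng.randint(1, 12))
            for s in sorted(rng.sample(range(0, 300), 25))
        ]
        rule_anns = [
            ann(s, s + rng.randint(1, 12), "rule")
            for s in sorted(rng.sample(range(0, 300), 25))
        ]
        merged = merge(dict_anns, rule_anns)
        for a, b in zip(merged, merged[1:]):
            assert not a.span.overlaps(b.span)
        again = merge(merged, [])
        assert [a.span for a in again] == [a.span for a in merged]


class TestMatching:
    def test_exact_match_counts(self):
        gold = [ann(0, 10, "gold")]
        pred = [ann(0, 10)]
        c = match_annotations(gold, pred, "strict")
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_partial_overlap_strict_vs_lenient(self):
        gold = [ann(0, 10, "gold")]
        pred = [ann(2, 8)]
        strict = match_annotations(gold, pred, "strict")
        lenient = match_annotations(gold, pred, "lenient")
        assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)
        assert (lenient.tp, lenient.fp, lenient.fn) == (1, 0, 0)

    def test_one_prediction_cannot_match_two_gold(self):
        gold = [ann(0, 10, "gold"), ann(20, 30, "gold")]
        pred = [ann(5, 25)]
        c = match_annotations(gold, pred, "lenient")
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_counts_are_consistent(self):
        rng = random.Random(7)
        gold = [ann(s, s + rng.randint(1, 9), "gold") for s in rng.sample(range(500), 40)]
        pred = [ann(s, s + rng.randint(1, 9)) for s in rng.sample(range(500), 40)]
        for mode in ("strict", "lenient"):
            c = match_annotations(gold, pred, mode)
            assert c.tp + c.fp == len(pred)
            assert c.tp + c.fn == len(gold)

    def test_strict_never_beats_lenient(self):
        rng = random.Random(13)
        for _ in range(20):
            gold = [ann(s, s + rng.randint(1, 9), "gold") for s in rng.sample(range(300), 20)]
            pred = [ann(s, s + rng.randint(1, 9)) for s in rng.sample(range(300), 20)]
            strict = match_annotations(gold, pred, "strict")
            lenient = match_annotations(gold, pred, "lenient")
            assert strict.tp <= lenient.tp
            assert strict.f1 <= lenient.f1

    def test_documents_scored_separately(self):
        gold = [ann(0, 10, "gold", doc_id="a")]
        pred = [ann(0, 10, doc_id="b")]
        c = match_annotations(gold, pred, "strict")
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)


class TestPrf:
    def test_hand_computed(self):
        c = compute_prf(EvaluationCounts(tp=8, fp=2, fn=2))
        assert (c.precision, c.recall, c.f1) == (0.8, 0.8, pytest.approx(0.8))

    def test_perfect_prediction(self):
        c = compute_prf(EvaluationCounts(tp=5, fp=0, fn=0))
        assert (c.precision, c.recall, c.f1) == (1.0, 1.0, 1.0)

    def test_zero_conventions(self):
        c = compute_prf(EvaluationCounts(tp=0, fp=0, fn=3))
        assert (c.precision, c.recall, c.f1) == (0.0, 0.0, 0.0)

    def test_small_grid_against_formulas(self):
        for tp in range(0, 6):
            for fp in range(0, 6):
                for fn in range(0, 6):
                    c = compute_prf(EvaluationCounts(tp=tp, fp=fp, fn=fn))
                    p = tp / (tp + fp) if tp + fp else 0.0
                    r = tp / (tp + fn) if tp + fn else 0.0
                    f1 = 2 * p * r / (p + r) if p + r else 0.0
                    assert (c.precision, c.recall, c.f1) == (p, r, f1)
                    assert 0.0 <= c.f1 <= 1.0


class TestAggregate:
    def test_hand_counted(self):
        anns = [
            ann(0, 1, "gold", doc_id="d1"),
            ann(2, 3, "gold", doc_id="d1"),
            ann(4, 5, "gold", doc_id="d1"),
            ann(0, 1, "gold", doc_id="d2"),
        ]
        # surfaces: A, A, B | B  (third doc empty)
        anns = [
            Annotation(a.doc_id, a.span, s, a.ann_type, a.score, a.source)
            for a, s in zip(anns, ["A", "A", "B", "B"])
        ]
        stats = aggregate_mentions(anns, n_docs=3)
        assert stats["total"] == 4
        assert stats["unique"] == 2
        assert stats["singletons"] == 0
        assert stats["mentions_per_doc"] == pytest.approx(4 / 3)

    def test_empty_corpus(self):
        stats = aggregate_mentions([], n_docs=0)
        assert stats["total"] == stats["unique"] == stats["singletons"] == 0

    def test_case_sensitivity_option(self):
        anns = [
            Annotation("d", Span(0, 3), s, "pathway_mention", None, "gold")
            for s in ["Wnt", "wnt"]
        ]
        assert aggregate_mentions(anns, n_docs=1)["unique"] == 2
        assert aggregate_mentions(anns, n_docs=1, case_sensitive=False)["unique"] == 1
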