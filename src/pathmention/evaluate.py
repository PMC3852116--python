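"""Merging of dictionary and rule annotation sets, and strict/lenient
precision-recall-F1 scoring against gold annotations.

Merging: annotations overlapping nothing pass through unchanged; transitively
overlapping groups are replaced by one annotation spanning the union, with
source ``merged``, score = max of member scores, and the entry id kept only
when exactly one member carries one.  The merged set is pairwise
non-overlapping.

Evaluation: strict matching requires exact span equality; lenient matching
accepts any overlap, paired one-to-one greedily in offset order so a single
prediction can never count against two gold spans.  P = TP/(TP+FP),
R = TP/(TP+FN), F1 = 2PR/(P+R), each 0 when its denominator is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import Annotation, Span

__all__ = [
    "EvaluationCounts",
    "merge",
    "merge_corpus",
    "match_annotations",
    "compute_prf",
    "aggregate_mentions",
    "evaluation_report",
]


@dataclass(frozen=True)
class EvaluationCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def compute_prf(counts: EvaluationCounts) -> EvaluationCounts:
    """Fill precision/recall/F1 from TP/FP/FN with 0-conventions for empty
    denominators."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return EvaluationCounts(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1)


def _merge_group(group: list[Annotation], text: Optional[str]) -> Annotation:
    if len(group) == 1:
        return group[0]
    start = min(a.span.start for a in group)
    end = max(a.span.end for a in group)
    scores = [a.score for a in group if a.score is not None]
    entry_ids = {a.entry_id for a in group if a.entry_id is not None}
    surface = text[start:end] if text is not None else ""
    return Annotation(
        doc_id=group[0].doc_id,
        span=Span(start, end),
        surface=surface,
        ann_type="pathway_mention",
        score=max(scores) if scores else None,
        source="merged",
        entry_id=next(iter(entry_ids)) if len(entry_ids) == 1 else None,
    )


def merge(
    dict_anns: Sequence[Annotation],
    rule_anns: Sequence[Annotation],
    text: Optional[str] = None,
) -> list[Annotation]:
    """Merge two annotation sets over one document into a non-overlapping set.

    ``text`` (the document text) is used to recover the surface string of
    newly created covering annotations; without it their surface is empty.
    All annotations must reference the same document.
    """
    combined = sorted(
        list(dict_anns) + list(rule_anns), key=lambda a: (a.span.start, a.span.end)
    )
    if not combined:
        return []
    doc_ids = {a.doc_id for a in combined}
    if len(doc_ids) > 1:
        raise ValueError(f"cannot merge annotations across documents: {sorted(doc_ids)}")
    merged: list[Annotation] = []
    group = [combined[0]]
    group_end = combined[0].span.end
    for ann in combined[1:]:
        if ann.span.start < group_end:  # transitive overlap chain continues
            group.append(ann)
            group_end = max(group_end, ann.span.end)
        else:
            merged.append(_merge_group(group, text))
            group = [ann]
            group_end = ann.span.end
    merged.append(_merge_group(group, text))
    return merged


def merge_corpus(
    dict_anns: Iterable[Annotation],
    rule_anns: Iterable[Annotation],
    texts: Optional[dict[str, str]] = None,
) -> list[Annotation]:
    """Merge per document over a whole corpus; ``texts`` maps doc_id to text."""
    by_doc: dict[str, tuple[list[Annotation], list[Annotation]]] = {}
    for ann in dict_anns:
        by_doc.setdefault(ann.doc_id, ([], []))[0].append(ann)
    for ann in rule_anns:
        by_doc.setdefault(ann.doc_id, ([], []))[1].append(ann)
    out: list[Annotation] = []
    for doc_id in sorted(by_doc):
        d, r = by_doc[doc_id]
        out.extend(merge(d, r, text=texts.get(doc_id) if texts else None))
    return out


def _match_doc_strict(gold: list[Span], pred: list[Span]) -> int:
    remaining = sorted(gold)
    tp = 0
    for span in sorted(pred):
        if span in remaining:
            remaining.remove(span)
            tp += 1
    return tp


def _match_doc_lenient(gold: list[Span], pred: list[Span]) -> int:
    gold_sorted = sorted(gold)
    taken = [False] * len(gold_sorted)
    tp = 0
    for span in sorted(pred):
        for i, g in enumerate(gold_sorted):
            if not taken[i] and span.overlaps(g):
                taken[i] = True
                tp += 1
                break
    return tp


def match_annotations(
    gold: Sequence[Annotation],
    pred: Sequence[Annotation],
    mode: str = "strict",
) -> EvaluationCounts:
    """Score predictions against gold annotations per document.

    ``strict`` counts exact span matches; ``lenient`` pairs each prediction
    (in offset order) with the first unmatched overlapping gold span.
    Counts are consistent: TP + FP = |pred| and TP + FN = |gold|.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    by_doc: dict[str, tuple[list[Span], list[Span]]] = {}
    for ann in gold:
        by_doc.setdefault(ann.doc_id, ([], []))[0].append(ann.span)
    for ann in pred:
        by_doc.setdefault(ann.doc_id, ([], []))[1].append(ann.span)
    tp = 0
    for doc_id, (g, p) in by_doc.items():
        tp += _match_doc_strict(g, p) if mode == "strict" else _match_doc_lenient(g, p)
    counts = EvaluationCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)
    return compute_prf(counts)


def aggregate_mentions(
    annotations: Sequence[Annotation],
    n_docs: Optional[int] = None,
    case_sensitive: bool = True,
) -> dict[str, float]:
    """Corpus-level mention statistics.

    ``unique`` counts lexicographically distinct surface strings (exact,
    case-sensitive comparison by default), ``singletons`` surfaces occurring
    exactly once; per-document means divide by ``n_docs`` (defaulting to the
    number of distinct doc ids seen, so documents without annotations must be
    counted via an explicit ``n_docs``).
    """
    surfaces = [
        a.surface if case_sensitive else a.surface.lower() for a in annotations
    ]
    if n_docs is None:
        n_docs = len({a.doc_id for a in annotations})
    counts: dict[str, int] = {}
    for s in surfaces:
        counts[s] = counts.get(s, 0) + 1
    total = len(surfaces)
    unique = len(counts)
    singletons = sum(1 for n in counts.values() if n == 1)
    return {
        "total": total,
        "unique": unique,
        "singletons": singletons,
        "mentions_per_doc": total / n_docs if n_docs else 0.0,
        "unique_per_doc": unique / n_docs if n_docs else 0.0,
    }


def evaluation_report(
    gold: Sequence[Annotation],
    predictions: dict[str, Sequence[Annotation]],
) -> pd.DataFrame:
    """Strict and lenient P/R/F1 for several prediction sets.

    ``predictions`` maps a method name (e.g. "baseline", "dictionary",
    "rules", "merged") to its annotation list; the result is one row per
    (method, mode) pair, the same shape as the standard NER benchmark table.
    """
    rows = []
    for method, pred in predictions.items():
        for mode in ("strict", "lenient"):
            c = match_annotations(gold, pred, mode=mode)
            rows.append(
                {
                    "method": method,
                    "mode": mode,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "recall": c.recall,
                    "precision": c.precision,
                    "f1": c.f1,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["method", "mode", "tp", "fp", "fn", "recall", "precision", "f1"],
    )
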