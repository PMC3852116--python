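"""Readers and writers for annotation interchange formats.

Two formats are supported:

* native standoff: a document is a ``<doc_id>.txt`` file paired with a
  ``<doc_id>.ann`` TSV (columns ``start  end  surface  ann_type  score
  source  entry_id``); whole corpora live in one directory.  A combined
  single-file TSV with a leading ``doc_id`` column is used for pipeline
  output.
* GATE standoff XML (reader only): ``GateDocument`` files whose
  ``TextWithNodes`` element interleaves text with ``<Node id=.../>`` markers
  and whose ``AnnotationSet`` elements reference node ids.  The annotation
  label that marks a pathway mention is configurable because gold corpora
  differ in their label inventories.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

from lxml import etree

from .types import Annotation, Span

__all__ = [
    "GoldFormatError",
    "write_annotations_tsv",
    "read_annotations_tsv",
    "write_standoff_corpus",
    "read_standoff_corpus",
    "read_gate_document",
    "read_gold_corpus",
]

_TSV_COLUMNS = ("doc_id", "start", "end", "surface", "ann_type", "score", "source", "entry_id")


class GoldFormatError(ValueError):
    pass


def _clean_field(value: str) -> str:
    return value.replace("\t", " ").replace("\n", " ").replace("\r", " ")


def _ann_row(ann: Annotation, with_doc_id: bool) -> str:
    fields = [
        str(ann.span.start),
        str(ann.span.end),
        _clean_field(ann.surface),
        ann.ann_type,
        "" if ann.score is None else f"{ann.score:.6f}",
        ann.source,
        ann.entry_id or "",
    ]
    if with_doc_id:
        fields.insert(0, ann.doc_id)
    return "\t".join(fields)


def _parse_row(
    fields: list[str], doc_id: Optional[str], path: Path, lineno: int
) -> Annotation:
    try:
        if doc_id is None:
            doc_id, rest = fields[0], fields[1:]
        else:
            rest = fields
        start, end = int(rest[0]), int(rest[1])
        surface, ann_type = rest[2], rest[3]
        score = float(rest[4]) if rest[4] else None
        source = rest[5]
        entry_id = rest[6] or None
    except (IndexError, ValueError) as exc:
        raise GoldFormatError(f"{path.name}:{lineno}: malformed row: {exc}") from exc
    return Annotation(
        doc_id=doc_id,
        span=Span(start, end),
        surface=surface,
        ann_type=ann_type,
        score=score,
        source=source,
        entry_id=entry_id,
    )


def write_annotations_tsv(annotations: Iterable[Annotation], path: str | Path) -> None:
    """Write a combined standoff TSV with a header and doc_id column."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for ann in sorted(annotations, key=lambda a: (a.doc_id, a.span.start, a.span.end)):
            fh.write(_ann_row(ann, with_doc_id=True) + "\n")


def read_annotations_tsv(path: str | Path) -> list[Annotation]:
    path = Path(path)
    out: list[Annotation] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("doc_id\t")):
                continue
            out.append(_parse_row(line.split("\t"), None, path, lineno))
    return out


def write_standoff_corpus(
    texts: dict[str, str],
    annotations: Iterable[Annotation],
    directory: str | Path,
) -> None:
    """Write one ``.txt`` + ``.ann`` pair per document into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_doc: dict[str, list[Annotation]] = {doc_id: [] for doc_id in texts}
    for ann in annotations:
        if ann.doc_id not in by_doc:
            raise GoldFormatError(f"annotation references unknown document {ann.doc_id!r}")
        by_doc[ann.doc_id].append(ann)
    for doc_id, text in texts.items():
        (directory / f"{doc_id}.txt").write_text(text, encoding="utf-8")
        rows = [
            _ann_row(a, with_doc_id=False)
            for a in sorted(by_doc[doc_id], key=lambda a: (a.span.start, a.span.end))
        ]
        header = "\t".join(_TSV_COLUMNS[1:])
        (directory / f"{doc_id}.ann").write_text(
            header + "\n" + "".join(r + "\n" for r in rows), encoding="utf-8"
        )


def read_standoff_corpus(
    directory: str | Path,
) -> tuple[dict[str, str], list[Annotation]]:
    """Read a directory of ``.txt``/``.ann`` pairs; validates offsets.

    Returns the documents' raw texts keyed by doc id (the file stem) and the
    annotation list.  A ``.txt`` without a ``.ann`` contributes a document
    with no annotations.
    """
    directory = Path(directory)
    txts = sorted(directory.glob("*.txt"))
    if not txts:
        raise GoldFormatError(f"no .txt documents found in {directory}")
    texts: dict[str, str] = {}
    annotations: list[Annotation] = []
    for txt in txts:
        doc_id = txt.stem
        text = txt.read_text("utf-8")
        texts[doc_id] = text
        ann_path = txt.with_suffix(".ann")
        if not ann_path.exists():
            continue
        with ann_path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or (lineno == 1 and line.startswith("start\t")):
                    continue
                ann = _parse_row(line.split("\t"), doc_id, ann_path, lineno)
                if ann.span.end > len(text):
                    raise GoldFormatError(
                        f"{ann_path.name}:{lineno}: span [{ann.span.start}, "
                        f"{ann.span.end}) exceeds document length {len(text)}"
                    )
                if ann.surface and text[ann.span.start : ann.span.end] != ann.surface:
                    raise GoldFormatError(
                        f"{ann_path.name}:{lineno}: surface mismatch at "
                        f"[{ann.span.start}, {ann.span.end})"
                    )
                annotations.append(ann)
    return texts, annotations


def read_gate_document(
    path: str | Path,
    label: str = "PathwayMention",
    doc_id: Optional[str] = None,
) -> tuple[str, list[Annotation]]:
    """Parse one GATE XML document; returns (text, gold annotations).

    Only annotations whose ``Type`` equals ``label`` are returned, as
    pathway-mention gold annotations with source ``gold``.
    """
    path = Path(path)
    doc_id = doc_id or path.stem
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise GoldFormatError(f"{path.name}: not well-formed XML: {exc}") from exc
    root = tree.getroot()
    twn = root.find("TextWithNodes")
    if twn is None:
        raise GoldFormatError(f"{path.name}: missing TextWithNodes element")
    pieces: list[str] = []
    offsets: dict[str, int] = {}
    pos = 0
    if twn.text:
        pieces.append(twn.text)
        pos += len(twn.text)
    for node in twn:
        node_id = node.get("id")
        if node_id is None:
            raise GoldFormatError(f"{path.name}: Node without id attribute")
        offsets[node_id] = pos
        if node.tail:
            pieces.append(node.tail)
            pos += len(node.tail)
    text = "".join(pieces)
    annotations: list[Annotation] = []
    for ann_el in root.iter("Annotation"):
        if ann_el.get("Type") != label:
            continue
        start_id, end_id = ann_el.get("StartNode"), ann_el.get("EndNode")
        if start_id not in offsets or end_id not in offsets:
            raise GoldFormatError(
                f"{path.name}: annotation references unknown node "
                f"{start_id!r}/{end_id!r}"
            )
        start, end = offsets[start_id], offsets[end_id]
        if not (0 <= start < end <= len(text)):
            raise GoldFormatError(
                f"{path.name}: annotation offsets [{start}, {end}) out of range "
                f"for text of length {len(text)}"
            )
        annotations.append(
            Annotation(
                doc_id=doc_id,
                span=Span(start, end),
                surface=text[start:end],
                ann_type="pathway_mention",
                score=None,
                source="gold",
            )
        )
    annotations.sort(key=lambda a: (a.span.start, a.span.end))
    return text, annotations


def read_gold_corpus(
    path: str | Path,
    format: str = "standoff",
    label: str = "PathwayMention",
) -> tuple[dict[str, str], list[Annotation]]:
    """Read a gold corpus in either supported format.

    ``standoff``: a directory of ``.txt``/``.ann`` pairs.  ``gate_xml``: one
    GATE XML file or a directory of them; ``label`` selects the annotation
    type that marks pathway mentions.
    """
    path = Path(path)
    if format == "standoff":
        return read_standoff_corpus(path)
    if format == "gate_xml":
        files = sorted(path.glob("*.xml")) if path.is_dir() else [path]
        if not files:
            raise GoldFormatError(f"no .xml documents found in {path}")
        texts: dict[str, str] = {}
        annotations: list[Annotation] = []
        for f in files:
            text, anns = read_gate_document(f, label=label)
            texts[f.stem] = text
            annotations.extend(anns)
        return texts, annotations
    raise ValueError(f"unknown gold format {format!r}; use 'standoff' or 'gate_xml'")
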