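"""Pathway-name dictionary: loading, acronym-variant expansion, indexing,
lexical profiling.

The dictionary file dialect is UTF-8 TSV: ``<source>:<accession><TAB><name>``
per line, ``#``-prefixed comment lines ignored.  The source database is
encoded in the identifier prefix.  Entries are indexed by lower-cased token so
the soft matcher can restrict candidate scoring to entries sharing vocabulary
with a query window; token document frequencies over the dictionary drive the
TFIDF weighting of the SoftTFIDF similarity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .text import is_punctuation, tokenize

__all__ = [
    "DictionaryEntry",
    "PathwayDictionary",
    "DictionaryFormatError",
    "load_dictionary",
    "write_dictionary",
    "generate_variants",
    "profile_tokens",
    "keyword_gene_composition",
]


class DictionaryFormatError(ValueError):
    """Raised for malformed or empty dictionary files."""


def _name_tokens(name: str) -> tuple[str, ...]:
    return tuple(tok.text.lower() for tok in tokenize(name))


@dataclass(frozen=True)
class DictionaryEntry:
    """One pathway name with its identifier and lower-cased token form."""

    entry_id: str
    name: str
    tokens: tuple[str, ...] = ()
    source_db: str = ""

    @classmethod
    def make(cls, entry_id: str, name: str) -> "DictionaryEntry":
        if not entry_id:
            raise ValueError("entry_id must be non-empty")
        base_id = entry_id.split("#", 1)[0]
        source = base_id.split(":", 1)[0] if ":" in base_id else ""
        return cls(
            entry_id=entry_id,
            name=name,
            tokens=_name_tokens(name),
            source_db=source,
        )


_PAREN_RE = re.compile(r"\s*\(([^()]*)\)")


def generate_variants(entry: DictionaryEntry) -> list[DictionaryEntry]:
    """Expand ``Long form (ACRO)``-shaped names into additional entries.

    For each parenthesized group the group content becomes a variant, and the
    name with every parenthesized group stripped becomes one more; names
    without parenthesized material produce nothing.  Variant identifiers are
    suffixed ``#v<k>`` to keep identifiers unique while preserving provenance.
    """
    groups = [g.strip() for g in _PAREN_RE.findall(entry.name)]
    groups = [g for g in groups if g]
    if not groups:
        return []
    stripped = _PAREN_RE.sub("", entry.name).strip()
    stripped = re.sub(r"\s{2,}", " ", stripped)
    names: list[str] = []
    if stripped and stripped != entry.name:
        names.append(stripped)
    names.extend(groups)
    variants = []
    seen = {entry.name.lower()}
    for k, name in enumerate(names, start=1):
        if name.lower() in seen:
            continue
        seen.add(name.lower())
        variants.append(DictionaryEntry.make(f"{entry.entry_id}#v{k}", name))
    return variants


class PathwayDictionary:
    """An indexed collection of :class:`DictionaryEntry`.

    ``token_index`` maps each lower-cased token to the set of entry ids
    containing it; ``doc_freq`` is the per-token entry count used as the
    document frequency in the TFIDF model (one dictionary entry = one
    "document").
    """

    def __init__(self, entries: Sequence[DictionaryEntry]):
        if not entries:
            raise DictionaryFormatError("dictionary has no entries")
        ids = [e.entry_id for e in entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DictionaryFormatError(f"duplicate entry ids: {dupes[:5]}")
        self.entries: tuple[DictionaryEntry, ...] = tuple(entries)
        self.by_id = {e.entry_id: e for e in self.entries}
        self.token_index: dict[str, frozenset[str]] = {}
        index: dict[str, set[str]] = {}
        for e in self.entries:
            for tok in set(e.tokens):
                index.setdefault(tok, set()).add(e.entry_id)
        self.token_index = {t: frozenset(s) for t, s in index.items()}
        self.doc_freq: dict[str, int] = {t: len(s) for t, s in self.token_index.items()}

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(sorted({e.source_db for e in self.entries}))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def load_dictionary(
    path: str | Path,
    expand_variants: bool = False,
    stop_entries: Optional[Iterable[str]] = None,
) -> PathwayDictionary:
    """Load a TSV pathway dictionary, optionally expanding acronym variants.

    Duplicate ``(id, name)`` lines are collapsed; a repeated id with a
    *different* name is an error.  ``stop_entries`` is an optional
    case-insensitive list of names to exclude (for suppressing generic,
    ambiguous entries such as "Disease" while keeping the file complete).
    """
    path = Path(path)
    stop = {s.strip().lower() for s in stop_entries} if stop_entries else set()
    entries: list[DictionaryEntry] = []
    seen_pairs: set[tuple[str, str]] = set()
    seen_ids: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise DictionaryFormatError(
                    f"{path.name}:{lineno}: expected '<id><TAB><name>', got {line!r}"
                )
            entry_id, name = fields[0].strip(), fields[1].strip()
            if (entry_id, name) in seen_pairs:
                continue
            if entry_id in seen_ids and seen_ids[entry_id] != name:
                raise DictionaryFormatError(
                    f"{path.name}:{lineno}: id {entry_id!r} repeated with a "
                    f"different name"
                )
            seen_pairs.add((entry_id, name))
            seen_ids[entry_id] = name
            if name.lower() in stop:
                continue
            entries.append(DictionaryEntry.make(entry_id, name))
    if not entries:
        raise DictionaryFormatError(f"{path.name}: no dictionary entries found")
    if expand_variants:
        expanded: list[DictionaryEntry] = []
        for e in entries:
            expanded.append(e)
            for v in generate_variants(e):
                if v.name.lower() not in stop:
                    expanded.append(v)
        entries = expanded
    return PathwayDictionary(entries)


def write_dictionary(dictionary: PathwayDictionary, path: str | Path) -> None:
    """Serialize back to the TSV dialect read by :func:`load_dictionary`."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for e in dictionary.entries:
            fh.write(f"{e.entry_id}\t{e.name}\n")


def profile_tokens(
    dictionary: PathwayDictionary, source_db: str = "all"
) -> pd.DataFrame:
    """Ranked token-frequency profile of one source database (or ``all``).

    Frequencies are lower-cased token occurrences over total token occurrences
    in the selected entries; pure-punctuation tokens are excluded.  Returns a
    DataFrame with columns ``token``, ``count``, ``percent`` sorted by
    descending count then token.
    """
    if source_db != "all":
        known = set(dictionary.sources)
        if source_db not in known:
            raise ValueError(
                f"unknown source {source_db!r}; known sources: {sorted(known)}"
            )
        selected = [e for e in dictionary.entries if e.source_db == source_db]
    else:
        selected = list(dictionary.entries)
    counts: dict[str, int] = {}
    total = 0
    for e in selected:
        for tok in e.tokens:
            if is_punctuation(tok):
                continue
            counts[tok] = counts.get(tok, 0) + 1
            total += 1
    rows = [
        {"token": tok, "count": n, "percent": 100.0 * n / total}
        for tok, n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["token", "count", "percent"])
    if not df.empty:
        df = df.sort_values(
            ["count", "token"], ascending=[False, True], ignore_index=True
        )
    return df


def keyword_gene_composition(
    dictionary: PathwayDictionary,
    keywords,
    recognizer,
) -> pd.DataFrame:
    """Per-source counts of entries containing pathway keywords and gene names.

    ``with_keyword`` counts entries whose name contains at least one keyword
    token or phrase; ``with_keyword_and_gene`` additionally requires at least
    one recognizer hit inside the name.  ``percent`` is the latter over the
    former (0 when the denominator is 0).  Variant entries (id containing
    ``#``) are excluded so each pathway is counted once.
    """
    from .rules import find_keywords
    from .text import preprocess

    per_source: dict[str, list[int]] = {}
    for e in dictionary.entries:
        if "#" in e.entry_id:
            continue
        row = per_source.setdefault(e.source_db, [0, 0, 0])
        row[0] += 1
        doc = preprocess(e.name, doc_id=e.entry_id)
        has_kw = any(find_keywords(s, keywords) for s in doc.sentences)
        if not has_kw:
            continue
        row[1] += 1
        if recognizer.tag(doc):
            row[2] += 1
    rows = []
    for source in sorted(per_source):
        total, with_kw, with_kw_gene = per_source[source]
        pct = 100.0 * with_kw_gene / with_kw if with_kw else 0.0
        rows.append(
            {
                "source": source,
                "total": total,
                "with_keyword": with_kw,
                "with_keyword_and_gene": with_kw_gene,
                "percent": pct,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["source", "total", "with_keyword", "with_keyword_and_gene", "percent"],
    )
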