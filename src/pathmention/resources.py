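"""Loaders for the data files bundled with the package."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


def _read_lines(name: str) -> tuple[str, ...]:
    text = resources.files("pathmention.data").joinpath(name).read_text("utf-8")
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return tuple(out)


@lru_cache(maxsize=None)
def default_stopwords() -> frozenset[str]:
    """Closed-class English stop-word list (lower-cased)."""
    return frozenset(w.lower() for w in _read_lines("stopwords.txt"))


@lru_cache(maxsize=None)
def default_gene_lexicon() -> tuple[str, ...]:
    """Bundled gene/protein symbol lexicon (case-sensitive entries)."""
    return _read_lines("gene_lexicon.txt")


def demo_dictionary_path() -> str:
    """Filesystem path of the bundled demo pathway dictionary."""
    return str(resources.files("pathmention.data").joinpath("demo_dictionary.tsv"))
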