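"""String similarity metrics: Jaro, Jaro-Winkler, TFIDF and SoftTFIDF.

SoftTFIDF is the hybrid token-bag similarity at the heart of the soft
dictionary matcher.  Given two token bags S (query) and T (dictionary entry),
each token ``w`` of S is paired with its Jaro-Winkler-closest token
``v*(w)`` of T; pairs at or above an inner threshold contribute

    V_S(w) * V_T(v*(w)) * JW(w, v*(w))

where V are the bags' unit-normalized TFIDF weight vectors.  TFIDF document
frequencies are counted over dictionary entries (one entry = one document):

    V'(w) = log(TF_w + 1) * log(N / df_w)

with ``df_w`` floored at ``df_floor`` for tokens unseen in the dictionary.
Tokens on the closed-class stop-word list and pure-punctuation tokens receive
zero weight, which is what lets the similarity absorb stop-word insertions,
deletions and word permutations in pathway names.  Comparisons are intended
to run on lower-cased tokens (the matcher lower-cases before calling in).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional

from .text import is_punctuation

__all__ = [
    "MetricConfig",
    "TfidfModel",
    "jaro",
    "jaro_winkler",
    "tfidf_vector",
    "softtfidf",
]


@dataclass(frozen=True)
class MetricConfig:
    """Jaro-Winkler constants and the inner SoftTFIDF pairing threshold.

    Defaults follow the classical Winkler parameterization: prefix scale
    ``p = 0.1``, prefix length capped at 4, inner pairing threshold 0.9.
    """

    jw_prefix_scale: float = 0.1
    jw_prefix_max: int = 4
    inner_jw_threshold: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.jw_prefix_scale <= 0.25):
            raise ValueError("jw_prefix_scale must lie in [0, 0.25]")
        if self.jw_prefix_max < 0:
            raise ValueError("jw_prefix_max must be >= 0")
        if not (0.0 <= self.inner_jw_threshold <= 1.0):
            raise ValueError("inner_jw_threshold must lie in [0, 1]")


DEFAULT_METRIC_CONFIG = MetricConfig()


def jaro(s: str, t: str) -> float:
    """Jaro similarity in [0, 1]; 0 if either string is empty or no match."""
    if not s or not t:
        return 0.0
    if s == t:
        return 1.0
    window = max(len(s), len(t)) // 2 - 1
    if window < 0:
        window = 0
    s_matched = [False] * len(s)
    t_matched = [False] * len(t)
    m = 0
    for i, ch in enumerate(s):
        lo = max(0, i - window)
        hi = min(len(t), i + window + 1)
        for j in range(lo, hi):
            if not t_matched[j] and t[j] == ch:
                s_matched[i] = True
                t_matched[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    transpositions = 0
    j = 0
    for i, ch in enumerate(s):
        if s_matched[i]:
            while not t_matched[j]:
                j += 1
            if ch != t[j]:
                transpositions += 1
            j += 1
    tau = transpositions / 2.0
    return (m / len(s) + m / len(t) + (m - tau) / m) / 3.0


@lru_cache(maxsize=1 << 18)
def _jw_cached(s: str, t: str, p: float, lmax: int) -> float:
    j = jaro(s, t)
    prefix = 0
    for a, b in zip(s, t):
        if a != b or prefix >= lmax:
            break
        prefix += 1
    return j + prefix * p * (1.0 - j)


def jaro_winkler(s: str, t: str, cfg: Optional[MetricConfig] = None) -> float:
    """Jaro-Winkler similarity: Jaro boosted by shared-prefix length."""
    cfg = cfg or DEFAULT_METRIC_CONFIG
    return _jw_cached(s, t, cfg.jw_prefix_scale, cfg.jw_prefix_max)


class TfidfModel:
    """Per-token IDF statistics over the dictionary's entries.

    ``n_docs`` is the number of dictionary entries, ``doc_freq`` the number of
    entries containing each token.  ``zero_weight_tokens`` (the stop-word
    list) are weighted as if present in every entry, i.e. zero.
    """

    def __init__(
        self,
        n_docs: int,
        doc_freq: Mapping[str, int],
        df_floor: int = 1,
        zero_weight_tokens: Iterable[str] = (),
    ):
        if n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if df_floor < 1:
            raise ValueError("df_floor must be >= 1")
        for tok, df in doc_freq.items():
            if not (1 <= df <= n_docs):
                raise ValueError(f"doc_freq[{tok!r}] = {df} outside [1, {n_docs}]")
        self.n_docs = n_docs
        self.doc_freq = dict(doc_freq)
        self.df_floor = df_floor
        self.zero_weight_tokens = frozenset(zero_weight_tokens)

    @classmethod
    def from_dictionary(
        cls,
        dictionary,
        df_floor: int = 1,
        stopwords: Optional[Iterable[str]] = None,
    ) -> "TfidfModel":
        if stopwords is None:
            from .resources import default_stopwords

            stopwords = default_stopwords()
        return cls(
            n_docs=dictionary.n_entries,
            doc_freq=dictionary.doc_freq,
            df_floor=df_floor,
            zero_weight_tokens=stopwords,
        )

    def raw_weight(self, token: str, tf: int) -> float:
        if tf <= 0:
            return 0.0
        if token in self.zero_weight_tokens or is_punctuation(token):
            return 0.0
        df = self.doc_freq.get(token, self.df_floor)
        if df >= self.n_docs:
            return 0.0
        return math.log(tf + 1.0) * math.log(self.n_docs / df)


def tfidf_vector(tokens: Iterable[str], model: TfidfModel) -> dict[str, float]:
    """Unit-Euclidean-norm TFIDF weights of a token bag.

    Returns a map over the bag's distinct tokens; an all-zero raw vector
    (e.g. a bag of stop-words only) comes back all-zero.
    """
    counts: dict[str, int] = {}
    for tok in tokens:
        counts[tok] = counts.get(tok, 0) + 1
    raw = {tok: model.raw_weight(tok, tf) for tok, tf in counts.items()}
    norm = math.sqrt(sum(w * w for w in raw.values()))
    if norm == 0.0:
        return {tok: 0.0 for tok in raw}
    return {tok: w / norm for tok, w in raw.items()}


def _best_partner(
    w: str,
    vt: Mapping[str, float],
    cfg: MetricConfig,
) -> Optional[tuple[str, float]]:
    """JW-closest token of T for ``w`` at or above the inner threshold.

    Ties on similarity prefer the larger T-weight, then the lexicographically
    smallest token, for determinism.
    """
    best: Optional[tuple[str, float]] = None
    for v in vt:
        sim = 1.0 if v == w else jaro_winkler(w, v, cfg)
        if sim < cfg.inner_jw_threshold:
            continue
        if best is None:
            best = (v, sim)
            continue
        bv, bs = best
        if sim > bs:
            best = (v, sim)
        elif sim == bs and (vt[v] > vt[bv] or (vt[v] == vt[bv] and v < bv)):
            best = (v, sim)
    return best


def softtfidf(
    S: Iterable[str],
    T: Iterable[str],
    model: TfidfModel,
    cfg: Optional[MetricConfig] = None,
) -> float:
    """SoftTFIDF similarity of two token bags, clamped to [0, 1]."""
    cfg = cfg or DEFAULT_METRIC_CONFIG
    vs = tfidf_vector(S, model)
    vt = tfidf_vector(T, model)
    return _soft_score(vs, vt, cfg)


def _soft_score(
    vs: Mapping[str, float], vt: Mapping[str, float], cfg: MetricConfig
) -> float:
    total = 0.0
    for w, ws in vs.items():
        if ws == 0.0:
            continue
        partner = _best_partner(w, vt, cfg)
        if partner is None:
            continue
        v, sim = partner
        total += ws * vt[v] * sim
    if total < 0.0:
        return 0.0
    # Self-matches accumulate to 1 only up to rounding in the vector norm;
    # snap near-1 totals so identical bags compare as exactly 1.0.
    if total >= 1.0 - 1e-12:
        return 1.0
    return total
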