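"""Independent reference implementations used as test oracles.

These transcribe the textbook definitions directly (explicit match/flag
arrays, nested loops over all token pairs, no caching, pruning or shared
helpers) so they exercise a code path fully separate from the package's
implementations.
"""

from __future__ import annotations

import math


def oracle_jaro(s: str, t: str) -> float:
    if len(s) == 0 or len(t) == 0:
        return 0.0
    if s == t:
        return 1.0
    window = max(max(len(s), len(t)) // 2 - 1, 0)
    s_flags = [False] * len(s)
    t_flags = [False] * len(t)
    matches = 0
    for i in range(len(s)):
        for j in range(max(0, i - window), min(len(t), i + window + 1)):
            if not t_flags[j] and s[i] == t[j]:
                s_flags[i] = True
                t_flags[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    s_matched = [s[i] for i in range(len(s)) if s_flags[i]]
    t_matched = [t[j] for j in range(len(t)) if t_flags[j]]
    half_transpositions = sum(a != b for a, b in zip(s_matched, t_matched))
    tau = half_transpositions / 2.0
    m = matches
    return (m / len(s) + m / len(t) + (m - tau) / m) / 3.0


def oracle_jaro_winkler(
    s: str, t: str, prefix_scale: float = 0.1, prefix_max: int = 4
) -> float:
    j = oracle_jaro(s, t)
    ell = 0
    for a, b in zip(s[:prefix_max], t[:prefix_max]):
        if a != b:
            break
        ell += 1
    return j + ell * prefix_scale * (1.0 - j)


def oracle_tfidf_weights(
    bag: list[str],
    n_docs: int,
    doc_freq: dict[str, int],
    stopwords: frozenset[str],
    df_floor: int = 1,
) -> dict[str, float]:
    counts: dict[str, int] = {}
    for tok in bag:
        counts[tok] = counts.get(tok, 0) + 1
    raw = {}
    for tok, tf in counts.items():
        if tok in stopwords or not any(ch.isalnum() for ch in tok):
            raw[tok] = 0.0
        else:
            df = doc_freq.get(tok, df_floor)
            raw[tok] = math.log(tf + 1.0) * math.log(n_docs / df) if df < n_docs else 0.0
    norm = math.sqrt(sum(w * w for w in raw.values()))
    if norm == 0:
        return {tok: 0.0 for tok in raw}
    return {tok: w / norm for tok, w in raw.items()}


def oracle_softtfidf(
    S: list[str],
    T: list[str],
    n_docs: int,
    doc_freq: dict[str, int],
    stopwords: frozenset[str],
    inner_threshold: float = 0.9,
    df_floor: int = 1,
) -> float:
    """Nested-loop SoftTFIDF over all token pairs, no indexing or pruning."""
    vs = oracle_tfidf_weights(S, n_docs, doc_freq, stopwords, df_floor)
    vt = oracle_tfidf_weights(T, n_docs, doc_freq, stopwords, df_floor)
    total = 0.0
    for w, ws in vs.items():
        if ws == 0.0:
            continue
        best = None
        for v in vt:
            sim = 1.0 if w == v else oracle_jaro_winkler(w, v)
            if sim < inner_threshold:
                continue
            if best is None:
                best = (v, sim)
                continue
            bv, bs = best
            if sim > bs or (sim == bs and (vt[v] > vt[bv] or (vt[v] == vt[bv] and v < bv))):
                best = (v, sim)
        if best is not None:
            v, sim = best
            total += ws * vt[v] * sim
    return max(0.0, min(total, 1.0))
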