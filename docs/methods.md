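# Methods

This note records the model, its parameters, the numerical choices, what the
synthetic corpora do and do not emulate, and the known limitations.

## Task and model

A *pathway mention* is a contiguous text span naming a biological pathway.
Named pathways are referred to with high surface variability — stop-word
insertion/deletion ("the complement cascade" / "complement cascade"),
preposition-driven permutation ("p53 signalling pathway" / "signalling
pathway of p53"), keyword alternation ("MAPK pathway" / "MAPK signalling
pathway") and British/American spelling ("signalling"/"signaling") — while
many occurrences of pathway keywords are not pathway mentions at all ("the
diagnostic pathway").  The recognizer therefore combines a variation-tolerant
dictionary matcher with precision-oriented contextual rules, and merges the
two annotation sets.  This dictionary + rules design is deliberate: curated
pathway-name inventories are large and well maintained, the linguistic
patterns of pathway naming are narrow and well understood, and no large
span-annotated training corpus exists that would favour a learned tagger.

## Soft dictionary matching

### SoftTFIDF

Token bags are compared with SoftTFIDF.  Per-token weights are
`V'(w) = log(TF_w + 1) · log(N / df_w)` scaled to unit Euclidean norm, with
`N` the number of dictionary entries and `df_w` the number of entries
containing `w`.  Design choices:

* **Unseen tokens** take `df = df_floor = 1` (the highest possible IDF):
  a token absent from the dictionary is maximally discriminative, so its
  presence in a window strongly penalises any match.
* **Stop-words and punctuation are weightless.**  Tokens on the bundled
  closed-class English stop-word list, and tokens containing no alphanumeric
  character, receive weight zero — equivalent to `df = N`.  This is the
  mechanism by which the similarity absorbs stop-word insertion, deletion
  and permutation: "signalling pathway of p53" and "p53 signalling pathway"
  are the same weighted bag.  Without this, an inserted "the" would get the
  *highest* weight in the window and veto the match.
* **Inner Jaro–Winkler pairing** uses the classical constants (prefix scale
  0.1, prefix cap 4, no high-Jaro precondition) and threshold
  `θ_jw = 0.9`; pairing ties prefer the larger target weight, then the
  lexicographically smaller token, for determinism.
* **Comparison is lower-cased** throughout, consistent with the dictionary
  index; original casing is preserved in output surfaces.
* The pairwise sum can exceed 1 when several query tokens soft-match one
  entry token; the score is clamped to `[0, 1]`.  Totals within `1e-12` of 1
  are snapped to exactly 1.0 so that identical bags — whose dot product
  equals 1 only up to rounding in the norm — compare as exact matches.

### Document scanning

* `lower_threshold = 0.40` gates start-point detection (a token anchors a
  window iff its single-token lookup is non-empty at this threshold) and
  window survival; `upper_threshold = 0.90` gates emitted matches.  Lowering
  the former costs speed, raising it costs recall; the latter trades
  precision against recall.  Both are configurable.
* Windows are anchored at the start point and grow rightward, one token at a
  time, to `max_window = 25` tokens — generous relative to the longest
  dictionary names so inserted stop-words still fit.  Growth aborts after
  more than `miss_limit = 4` consecutive window lengths with empty lookups
  (i.e. on the fifth miss).  Per start point, the *longest* window whose best
  score clears the upper threshold yields one annotation.
* Windows never cross sentence boundaries and exclude sentence-final
  terminator/separator punctuation (a closing bracket may legitimately end
  an acronym-bearing name and is kept).
* **Edge trimming.**  Because trailing stop-words are weightless, the
  longest-window rule would otherwise always swallow them ("MAPK signalling
  pathway is" scores exactly what "MAPK signalling pathway" scores).
  Trailing stop-word and punctuation tokens are therefore trimmed from the
  emitted span; a `)` that closes a `(` inside the window is kept.
* **Overlap resolution** across start points keeps the highest score, then
  the longer span, then the leftmost.  This lets an exact full-name window
  (score 1.0) displace partial windows anchored mid-name.
* Candidate pruning restricts scoring to entries sharing at least one token
  — or a Jaro–Winkler-close token — with the window; per-token close sets
  are cached per matcher.  Pruning is exact: an entry can score above zero
  only through such a token, so pruned lookup equals brute-force scoring
  over all entries (asserted in the tests).

## Rule component

* Keywords: `pathway(s)`, `signalling`/`signaling`, `transduction`,
  `cascade(s)`, `network(s)`, plus multi-token combinations including plural
  forms ("signalling pathways", "signal transduction pathway", …).  At any
  position the longest combination wins and its tokens are not re-matched,
  so coordinated heads like "… signalling pathways" anchor one segment, not
  two.
* Backward extension stops at the first determiner (DT/PDT), separator
  (comma, period, semicolon, colon), preposition/subordinating conjunction
  (IN), wh-word (WDT/WP/WP$/WRB) or verb (VB*), or at the sentence start.
  **Gene mentions are atomic during the scan**: tokens covered by a
  gene/protein annotation are skipped as a block, so the "of" inside
  "mammalian target of rapamycin" cannot terminate the scan.  This is what
  lets the rules capture long coordinated mentions such as
  "ras/raf/MAPK kinase (MEK)/ERK and phosphatidylinositol 3-kinase
  (PI-3K)/AKT/mammalian target of rapamycin (mTOR) signalling pathways".
  Scanning stops only at the five classes above — not at other entity
  boundaries or at further keywords.
* Forward extension fires only when the tokens immediately after the anchor
  begin a pathway verb phrase ("induced by", "regulated by", "mediated
  through", …; the list is config-extensible) and runs to the token before
  the next punctuation.
* The gene gate requires a gene mention **wholly inside** the segment (not
  merely overlapping).  The bundled recognizer combines case-sensitive
  token-sequence matches against a curated lexicon (including multi-word
  protein names) with a morphology heuristic (tokens mixing upper-case
  letters and digits, length ≥ 2, not stop-listed).  Any external tagger can
  replace it through the recognizer interface or by importing standoff
  annotations.
* Hyphenated forms: the tokenizer splits on hyphens, so "Wnt-signalling"
  exposes both the gene token and the keyword to the rules.  This is a fixed
  package-wide convention.

## Merging and evaluation

* Merging closes overlap chains transitively over the combined annotation
  set and replaces each multi-member group by one annotation spanning the
  union (source `merged`, score = max member score, entry id kept only when
  exactly one member has one).  Singleton groups pass through unchanged.
  The output is pairwise non-overlapping and merging is idempotent.
* Strict matching counts exact span equality (per document, as a multiset);
  lenient matching pairs predictions one-to-one with the first unmatched
  overlapping gold span in offset order, so one prediction spanning two gold
  mentions counts once — preventing double-counting inflation.  Zero
  denominators yield zero by convention.
* "Unique mentions" in corpus statistics means exact, case-sensitive surface
  distinctness; a case-insensitive mode is provided.

## POS tagging

The tagger is a pluggable backend (any callable from token sequences to Penn
Treebank tags).  The bundled backend is a deterministic lexicon + suffix
tagger whose coverage is tuned to the five token classes the rules consume;
open-class words default to noun tags, which cannot spuriously terminate a
backward scan.  `-ing` forms are verbs unless noun-listed
("signalling"/"signaling" in particular), `-ed` forms are verbs.  This keeps
the pipeline fully reproducible with no model downloads; a statistical
tagger can be plugged in where higher tagging accuracy matters.

## Synthetic corpora

The generator embeds dictionary names in carrier sentences and records gold
spans exactly.  It emulates: verbatim mentions, single stop-word insertion
and deletion, keyword-tail permutation into prepositional form, keyword
alternation, spelling swaps, ambiguous-keyword distractor sentences with no
gene context, and rule-only mentions (gene + keyword phrases absent from the
dictionary).  Deliberate simplifications:

* Carrier templates place only stop-words and punctuation after the embedded
  mention, so the longest-window rule cannot legitimately extend a match
  past the gold span; carrier gene symbols are chosen to have no
  Jaro–Winkler-close token in the demo dictionary's vocabulary, so an
  adjacent gene cannot glue onto a mention's window.  Real text offers no
  such guarantees — a mention followed by a content word that soft-matches
  the same entry can be over-extended, and strict (not lenient) scores
  suffer accordingly.
* One mention per sentence, no nested or abbreviated mentions, no
  acronym-expansion phenomena, simplified grammar.

Passing tests on these corpora therefore demonstrate the algorithmic
contracts (variation tolerance, gating, merging algebra), not performance on
natural prose.  Scores on real gold corpora depend on the dictionary, the
gene recognizer and the tagger actually plugged in.

The generation is a pure function of (dictionary, configuration, seed); the
same seed gives byte-identical corpora.  The bundled 254-entry demo
dictionary contains realistic human pathway names in the style of six public
databases and is a hand-curated demo artifact, not a database export.

## Degenerate inputs and numeric conventions

* Empty text tokenizes to nothing; unterminated text is one sentence.
* A dictionary must be non-empty with unique entry ids; duplicated
  `(id, name)` lines collapse; an id repeated with a different name is an
  error.  With a single-entry dictionary every IDF is `log(1) = 0`, all
  vectors are zero and soft matching finds nothing — TFIDF needs contrast.
* Token bags whose raw weights are all zero yield zero vectors and score 0
  against everything; single-token lookups of stop-words or punctuation are
  therefore always empty.
* Lookup results require a strictly positive score even at threshold 0.
* All randomness flows through explicit seeds; no global random state.

## Known limitations

* Whether a token can *anchor* a window depends on its discriminative weight
  in some entry; a mention whose first token is weak everywhere (e.g. bare
  "signalling" under unfavourable dictionary statistics) can only be entered
  mid-name, and the recovered span may then start past the gold start.
* No linking/normalization of mentions to database entries beyond carrying
  the best-matching entry id; resolving "the CD2 pathway" to a dictionary
  entry like "Cell adhesion molecules (CAMs)" needs background knowledge the
  package does not model.
* No acronym expansion ("T cell receptor (TCR) signalling"), and mentions
  with neither a keyword nor a dictionary correlate ("microglial
  activation") are unreachable by design.
* The bundled gene lexicon and morphology heuristic are deliberately small
  and deterministic; missed gene names suppress rule recall, and false gene
  hits can admit false rule segments.
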