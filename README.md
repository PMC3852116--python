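# pathmention

Named-entity recognition of **biological pathway mentions** in biomedical
text — spans such as *"MAPK signalling pathway"*, *"Wnt cascade"* or
*"signalling pathway of p53"* that refer to a named pathway rather than
describing its molecular constituents.  The package is aimed at curators of
pathway databases and systems biologists who want to ask questions like
*"which pathways does the literature associate with this disease?"* over
large article collections.

## Method

Two complementary recognizers run over POS-tagged text and their outputs are
merged:

**Soft dictionary matching.**  A pathway-name dictionary (TSV of
`source:accession <TAB> name`) is indexed by token.  Candidate text windows
are scored against entries with **SoftTFIDF**, the hybrid of TFIDF weighting
and Jaro–Winkler string distance: for query bag *S* and entry bag *T*,

```
sim(S, T) = Σ_{w ∈ S, JW(w, v*(w)) ≥ θ_jw}  V_S(w) · V_T(v*(w)) · JW(w, v*(w))
```

where `v*(w)` is the Jaro–Winkler-closest token of *T*, `θ_jw = 0.9`, and
`V(w)` are unit-normalised `log(TF+1)·log(N/df)` weights with document
frequencies counted over the dictionary's *N* entries.  Scanning a document,
every token whose single-token lookup clears a **lower threshold** (0.40)
anchors candidate windows of growing length (up to 25 tokens; growth stops
after more than 4 consecutive empty lengths); the longest window whose best
match clears an **upper threshold** (0.90) is emitted.  Because closed-class
stop-words carry zero weight and scoring is bag-based, the matcher absorbs
stop-word insertion/deletion, word permutation and (via the Jaro–Winkler
inner matches) spelling variation — exactly the variations that defeat exact
dictionary matching.

**Keyword + POS rules gated on genes.**  Pathway keywords ("pathway",
"signalling", "cascade", "network", "transduction" and their combinations)
anchor segments that are extended leftward to the nearest determiner,
separator, preposition/subordinating conjunction, wh-word or verb, and
rightward through pathway verb phrases ("regulated by …") up to the next
punctuation.  A segment counts as a pathway mention only if a gene/protein
mention lies wholly inside it, which discards ambiguous keyword uses such as
*"the diagnostic pathway"*.  Gene mentions come from a pluggable recognizer;
a deterministic lexicon + morphology tagger is bundled, and standoff
annotations from an external tagger can be imported.

**Merging and evaluation.**  Overlapping annotations from the two components
are replaced by one covering annotation; disjoint ones pass through.
Predictions are scored against gold corpora under **strict** (exact span)
and **lenient** (any overlap, one-to-one) regimes with
`P = TP/(TP+FP)`, `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`.

## Worked example

```python
from pathmention import PathwayTagger, load_dictionary
from pathmention.resources import demo_dictionary_path

tagger = PathwayTagger(load_dictionary(demo_dictionary_path()))
doc = tagger.prepare(
    "We found that TP53 loss activated the signalling pathway of p53 in these cells."
)
for ann in tagger.tag(doc):
    print(ann.surface, ann.source, ann.score, ann.entry_id)
```

prints

```
signalling pathway of p53 dictionary 1.0 PO:0000718
```

The permuted surface form never occurs in the dictionary (the entry is
*"p53 signalling pathway"*), yet SoftTFIDF scores the token bag at 1.0 — the
zero-weight preposition changes nothing and the bag ignores word order — and
links the span to the entry `PO:0000718`.  Exact dictionary matching (the
`baseline` component) misses it entirely.  The annotation keeps its
`dictionary` provenance because no rule annotation overlaps it here; when
both components fire on overlapping spans, the merged annotation covers
both and is marked `merged`.

The same pipeline is available from the shell:

```sh
pathmention synth --dict demo.tsv --n 100 --seed 3 --out corpus/
pathmention tag --dict demo.tsv --in corpus/ --out predictions.tsv
pathmention evaluate --gold corpus/ --pred predictions.tsv --mode both
```

## Layout

| module | contents |
|---|---|
| `pathmention.text` | tokenizer, sentence splitter, rule-based POS tagger, span data model |
| `pathmention.dictionary` | dictionary loading, acronym-variant expansion, lexical profiling |
| `pathmention.metrics` | Jaro, Jaro–Winkler, TFIDF, SoftTFIDF |
| `pathmention.matcher` | windowed soft dictionary scan, exact-match baseline |
| `pathmention.rules` | keyword/POS rules, gene recognizers |
| `pathmention.evaluate` | merging, strict/lenient P/R/F1, mention statistics |
| `pathmention.gold_io` | standoff TSV and GATE XML readers/writers |
| `pathmention.synth` | synthetic corpus generator |
| `pathmention.cli` | `pathmention` command-line interface |

See `docs/methods.md` for modelling choices, parameter defaults and known
limitations.
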