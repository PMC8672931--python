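# Methods

## Document model and corpus I/O

A corpus is a set of documents (id, title, abstract, ordered
section-labelled paragraphs, publication year, venue) plus a flat table of
in-text citation mentions.  Publication dates are truncated to the year;
the citation recency term only uses year granularity, so nothing finer is
stored.  Missing years are kept missing rather than imputed and make the
recency denominator fall back to 1.

Citation resolution matches any identifier a bibliography entry exposes
(DOI, internal id, ...) case-insensitively against the identifiers of
corpus documents.  Spans that do not resolve are retained with an
unresolved marker so mention counts remain faithful to the source, but
they never contribute to edge weights.  Section headings are normalized
(lowercase, punctuation and numbering stripped) and mapped through an
alias table to section classes; anything unrecognized is treated as the
"other" class by the section-weighting step.  Duplicate records of the
same work under different ids are treated as distinct documents —
deduplication across preprint/published versions is out of scope.

## C-value term extraction

Candidates are maximal `(ADJ|NOUN)+ NOUN` token runs and all their
contiguous subsequences, with length bounds 2–6 words: unigrams are
excluded because `log2(1) = 0` makes them degenerate under the scoring
formula, and runs longer than 6 words in these corpora are almost always
chunking artifacts.  The built-in tagger is deliberately lightweight — a
stopword/number/single-letter filter marks chunk breaks and every
remaining content token is treated as a noun — because the scoring layer
is tagger-independent: `candidates_from_tagged` accepts pre-tagged text
for callers with a trained tagger, and the test suite uses pre-tagged
fixtures where the pattern itself matters.

Frequencies count every occurrence of a word sequence, standalone or
nested inside a longer candidate, within a single document.  Scoring is
per document (the document-graph weights need per-document C-values);
collection-level importance is the sum of per-document scores, which feeds
the top-terms listing and the bubble-cloud export.  Negative raw values —
possible when a candidate's containing terms are counted with different
conventions — are clamped to 0.  Ties are broken alphabetically so output
is a pure function of the candidate multiset.  No stemming or variant
clustering is applied; terms are reported verbatim.

## Indexing and retrieval

The four unit schemes (full text; title+abstract; paragraph;
first+last sentence per paragraph) share one tokenizer: lowercase, strip
punctuation, keep internal hyphens, no stemming, no stop-word removal.
This keeps scores transparent and exactly recomputable by hand.  Sentence
splitting uses terminal-punctuation boundaries with a small abbreviation
guard list; a one-sentence paragraph contributes that sentence once.

BM25 uses k1 = 1.2, b = 0.75 and the non-negative idf variant
`ln(1 + (N − df + 0.5)/(df + 0.5))`, so a unit containing at least one
query token always scores strictly above zero and documents with no
matching tokens are simply absent from the ranking.  Sub-document unit
scores aggregate to documents by maximum — the standard passage-retrieval
choice, preferring a document with one strongly matching passage over one
with diffuse weak matches.  Ranking ties break by doc id.

Term-based reranking scores each ranked document by the summed C-value of
its profile terms occurring as substrings of the normalized query, then
combines `(1 − λ)·minmax(BM25) + λ·minmax(overlap)` with λ = 0.5 by
default.  A constant score vector min-max-normalizes to zeros, so the
other component decides; λ = 0 short-circuits to the input ordering.  The
C-value weighting of the overlap (rather than raw term frequency) keeps
the reranker consistent with the term profiles used everywhere else.

## Document graph

Term edges connect every pair of retrieved documents sharing a term in
both top-T profiles (T = 10 by default, bounding the worst case of
pairs × terms); each shared term yields its own parallel edge with weight
`(Cvalue_t(a) + Cvalue_t(b))/2` and the term as label.  Direct citation
edges weigh citation frequency N, the maximum section weight among the
pair's mentions, and the publication-year gap:
`N · max_i(sw_i) / max(1, year_a − year_b)`.  Default section weights are
0.5 for introduction, related-work and background citations and 1.0
otherwise — the literature on citation zoning agrees on the direction of
the effect but not a magnitude, so the values are configurable.
Co-citation edges average the pairwise direct-citation strength toward the
common reference set: `Σ_{c∈C}(wcd_ac + wcd_bc)/(2·|C|)`, read as a
symmetric mean over C; the shared references need not be graph nodes.

All edges are directed from the newer to the older publication (citation
edges follow citation order).  Equal or missing years fall back to the
lexicographically smaller doc id as source, making direction total and
deterministic.  Negative year gaps (a "cited" paper dated later, as
happens with preprints) floor to 1 like same-year citations.

Nodes carry the query-relevance score (retrieval score; node size in a
front end) and an origin flag.  Expansion ranks all out-of-graph corpus
documents by their strongest edge to the selected node and admits the top
m with origin `expanded` and relevance 0 — they were not retrieved, and
the flag preserves the visual distinction between initial and expanded
nodes.  Threshold filtering keeps edges with weight ≥ τ and never drops
nodes.  Export formats are d3-compatible node-link JSON and GraphML
(via networkx); import–export round-trips reproduce the graph exactly.

## IR evaluation

nDCG uses linear gain `rel_r / log2(r + 1)` with the ideal computed from
the grades sorted descending; AP is truncated at rank K but normalized by
the total relevant count R (the `map_cut` convention); P@N binarizes at
grade ≥ 1.  Default cutoff 10.  Topics with no relevant documents have
undefined nDCG/AP and are excluded from all means rather than scored 0.

## Synthetic corpora

The generator emulates exactly the structure the pipeline depends on:

- filler text over a synthetic vocabulary with a Zipf-like frequency
  profile (exponent 1.1) whose head ranks are occupied by real function
  words — as in natural language — so that chunk-breaking stopwords are
  frequent, filler n-grams stay low-C-value, and idf varies across tokens;
- planted multi-word phrases at controlled per-document frequencies, each
  occurrence a standalone sentence: the first at the end of a body
  paragraph, the second in the abstract, later ones at paragraph
  boundaries, so every indexing scheme observes a planted phrase once its
  frequency reaches 2;
- 2–6 paragraphs per document with section labels drawn from a
  configurable distribution; citations Poisson-distributed (default mean 3
  per document) toward same-year-or-older documents, so the strictly-older
  citation subgraph is acyclic while same-year pairs exercise the
  `max(1, ·)` recency floor;
- years uniform over a configurable range (default 2000–2021, the modern
  corpus the tool targets), 200 documents and a 500-word vocabulary by
  default — large enough for non-trivial rankings, small enough that any
  check reruns in seconds.

Everything derives from a single seeded generator, so a config is a
complete, byte-reproducible description of a corpus.  Relevance judgments
are derived from the generated text (verbatim phrase containment →
grade 2, at least half the query's tokens → grade 1), mirroring a graded
TREC-style assessment with a known answer key.

What the generator does *not* emulate: real word order and syntax,
polysemy and term variants, realistic citation topology (no preferential
attachment or community structure), author/venue effects, and OCR noise.
Tests passing on these corpora therefore demonstrate the correctness of
the formulas, contracts and invariants — not retrieval quality on real
literature, which additionally depends on tagging quality and corpus
statistics that only real data provides.

## Numerical and degenerate-input choices

- C-value clamping at 0; ties alphabetical; score lists are
  permutation-stable functions of the candidate multiset.
- Empty text → empty candidate list; stop-word-only documents have empty
  profiles; an empty document set is a validation error for aggregation.
- Queries with no indexed tokens return an empty ranking, not an error.
- Metadata rows without an id are skipped and counted, not fatal;
  duplicate ids are fatal and name the id.
- Graph worked values (term (4.0+2.0)/2 = 3.0; direct 3·1.0/2 = 1.5;
  indirect 5.0/4 = 1.25) are asserted exactly; oracle-equivalence checks
  use 1e-9/1e-12 absolute tolerance on accumulated floating-point sums.

## Problem sizes

The default verification corpus is 200 documents with 7 planted phrases;
edge-formula cross-checks run on 1000 randomized 6-document instances; the
C-value oracle sweep uses 150 random documents with at most 50 candidates
each.  These sizes give each statistic enough support while keeping the
whole suite and the acceptance script in the seconds range.

## Known limitations

- The heuristic tagger over-generates noun phrases on real prose compared
  with a trained POS tagger; C-value ordering is robust to this but
  absolute scores shift.
- Per-document C-value scoping means a term's collection importance is a
  sum of within-document scores, not a single collection-level C-value;
  the two orderings can differ for terms concentrated in few documents.
- The reranker's overlap test is substring containment in the normalized
  query, so profile terms that paraphrase the query contribute nothing.
- GraphML export stringifies attribute types per the GraphML schema;
  round-trips preserve values but not Python numeric subtypes.
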