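# Methods

This note records the modeling choices behind `halprf`, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Text analysis and index

Documents are lowercased, NFC-normalized, split on non-alphanumeric
characters, optionally stopword-filtered, and Porter-stemmed (the classic
five-step 1980 algorithm, implemented in `halprf.porter` and checked against
published reference word/stem pairs). Token positions are 0-based indices
into the post-analysis stream; the distance between two occurrences is the
absolute position difference, so adjacent tokens are at distance 1.
Stopword removal is **off by default**: deleting tokens shortens distances
and therefore changes every proximity weight, so it should be a deliberate
choice.

The positional inverted index keeps per-document token lists so feedback
documents can be window-scanned without re-reading the corpus; collection
statistics are `N` (document count), `df`, `cf`, and `avg_dl`.

**IDF.** The retrieval-model family here never fixes one IDF formula, so we
use the BM25-consistent `log((N − df + 0.5)/(df + 0.5))` floored at 0
everywhere (retrieval, feedback weights, and the proximity weight), with
`log(N/df)` available via `idf(..., scheme="plain")`. Unseen terms get 0 by
default (`unseen="max"` opts into the df=0 value). The floor means query
terms occurring in more than half the collection contribute nothing — on
very small test collections this is the first thing to check when a score
is unexpectedly zero.

## First-pass ranking

BM25 uses `k1 = 1.2`, `k3 = 8` (standard strong-baseline settings; `b`
defaults to 0.5 and is meant to be swept over 0..1). The query-side
saturation factor is the standard `(k3+1)·qtf/(k3+qtf)`; some printed
sources give the denominator as `k3·qtf`, which is constant in `qtf` and
inconsistent with the Okapi literature — `BM25Params(as_printed=True)`
reproduces that variant for auditability, and is not used anywhere else.

The Dirichlet language model scores by query log-likelihood with prior mass
`mu` (default 2000, a common optimum on biomedical full text). Query terms
absent from the entire collection are skipped — they carry no ranking
information — rather than contributing −∞; with `mu = 0` a term absent from
a document legitimately yields −∞ and the document is dropped from the
ranking.

BM25 scores only documents sharing a query term; documents scoring ≤ 0 are
not retrieved. The language model scores all documents. Ties are broken
lexicographically by document id, so every run is deterministic and
byte-stable across platforms (scores serialize at 6 decimals).

## Proximity weights

The sliding window is **symmetric**: occurrences of the candidate on either
side of a query-term occurrence count, because the feedback model only
consumes the combined count. (The original semantic-space construction is
directional — `cooccurrence_matrix` exposes that row/column view for
inspection.) All occurrence pairs within distance `D` count, not only
nearest neighbours, and windows truncate at document boundaries with no
special treatment. `HAL(t, q)` sums `w(l)·p(t,l,q)` with `w(l) = D − l + 1`;
`W_HAL(t, Q0)` multiplies each query term's HAL score by its IDF and sums —
the per-query-term reading of the weight (the alternative reading, a single
whole-query HAL score scaled by each IDF, would make the sum a constant
times `Σ IDF(q_i)` and discard the per-term distinction the IDF factor is
there to provide).

**Adaptive windows.** `f1(dl) = dl`, `f2(dl) = dl·(1 + dl/avg_dl)`,
`f3(dl) = (dl + avg_dl)/(1 + log2(dl/avg_dl))`, each rounded to the nearest
integer and floored at 1, computed per feedback document against the
whole-collection `avg_dl`. The `f3` expression is sometimes printed without
parentheses; the reading adopted here keeps the function finite and
length-increasing near `dl = avg_dl`. Its denominator turns non-positive
for documents shorter than `avg_dl/2`; such documents fall back to `f1`
with a logged warning.

## Expansion

The per-document feedback weight `r(t)` is the document-side BM25 factor
`(k1+1)·tf/(K+tf)·IDF(t)` — the query-side `(k3, qtf)` factor is meaningless
for terms not in the query. Candidates are all feedback-document terms
minus the original query terms. Both the mean-BM25 and mean-HAL vectors are
normalized **across the candidate axis** (not per document) so the two
components are commensurable before the β-mix; candidates are ranked by the
combined bracketed score after normalization, truncated to the expansion
budget (ties broken lexicographically), and merged with `(1−α)·Q0`.

Degenerate cases: α = 0 returns Q0 unchanged; an all-zero proximity
component (e.g. no query term occurs in the feedback set) falls back to the
β = 0 branch with a warning; min-max normalization of a constant vector
returns zeros with a warning. Zero-weight entries are never retained in a
query vector, so the min-max minimum candidate can drop out of the expanded
query — harmless, as its weight is exactly 0.

The second pass is BM25 with the expansion weights as fractional query term
frequencies: the feedback loop's first pass is BM25, so re-scoring with the
same model keeps the comparison between expansion engines clean.

## Evaluation

MAP, P@{5,10,20}, recall and F1 follow trec_eval conventions: unjudged
documents are non-relevant, graded judgments binarize at grade > 0, topics
without relevant documents are dropped with a warning. Recall — and hence
F1 = 2PR/(P+R) — is computed at the same cutoff as MAP (1000). At that
cutoff precision is necessarily small on collections with few relevant
documents, so F1 is near-constant on the synthetic benchmarks; it becomes
informative on larger judged sets. Cross-validation splits topics by the
parity of their numeric component; hyper-parameters are selected on the
training fold only and applied once to the held-out fold. Wilcoxon
signed-rank and paired-t p-values are both reported (delegated to scipy),
since either is a defensible choice for per-topic metric pairs.

## Synthetic collections

The generator plants, per topic: *easy relevant* documents (query terms
twice, expansion terms adjacent to them), *hard relevant* documents (query
terms once — under-ranked by the first pass — expansion terms three times,
again adjacent), *near-miss non-relevant* documents (the same query and
expansion terms separated by at least `nonrelevant_gap` tokens, plus two
distractor terms at high frequency), *distractor-only* documents, and
background filler. Placement is distance-exact; all randomness flows
through one seeded generator, and output is byte-identical per seed.

This construction makes proximity, not frequency, the signal separating
good expansion terms from distractors: near-miss documents rank high in the
first pass and drag their distractors into the feedback set, where a
frequency-only engine selects them and retrieves the distractor-only
documents, while the sliding window scores them at zero. The default scale
(500 documents, 20 topics, lengths 70–90, `relevant_gap` 3,
`nonrelevant_gap` 15 = 3× the default window) was fixed at design time from
this analysis and not revisited.

What a green directional test establishes: with proximity structure present
and a window smaller than the planted separation, proximity-weighted
selection beats frequency-only selection. What it does not establish:
anything about real clinical text — the generator has no term-frequency
skew matching natural language, no topical vocabulary overlap between
topics, no graded relevance, and document lengths two orders of magnitude
below full-text articles. In particular the adaptive-window variants, whose
point is matching `D` to documents thousands of tokens long, are *expected*
to do poorly here: `D = dl` spans the whole synthetic document, so the
planted 15-token separation falls inside the window and the distractor
filter disappears. The directional claim is therefore asserted for the
fixed-window engine only.

Benchmark configuration, chosen a priori with the generator design:
`α = 0.5` (equal weight to original query and feedback), `β = 0.7`
(selection dominated by proximity evidence — the property under test),
`|R| = 5` feedback documents, expansion budget 2 (the number of planted
expansion terms), `D = 5` (the worked-example window, well below the
planted non-relevant gap).

## Known limitations

- The index is fully in-memory and per-document token lists are retained;
  fine for the collection sizes the library targets (≤ ~10^5 short
  documents), not for a million-document full-text corpus.
- No incremental indexing; `build_index` consumes a complete stream.
- The feedback candidate pool is the full feedback vocabulary; no frequency
  floor or stoplist is applied before scoring, which can admit one-off
  rare tokens when the feedback set is tiny.
- F1 at cutoff 1000 (see above) is near-degenerate on small collections.
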