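# Methods

## Problem setting

Dataset discovery indexes hold metadata records — titles, descriptions,
organism and assay fields — rather than full text, and the people searching
them rarely use the same surface vocabulary as the depositors. This is the
classic vocabulary-mismatch failure mode, and the toolkit implements one
widely used remedy: automatic query expansion with synonyms from a curated
controlled vocabulary (MeSH), added as an optional, down-weighted clause so
that well-matched synonyms help while poorly matched ones cost little.

## Corpus model and indexing

Records arrive as arbitrarily nested JSON. Each record is flattened to
`dot.separated.path → text` pairs: list indices are dropped, sibling values
under the same path are space-joined, and numbers keep their source lexical
form (the JSON parser is configured to hand them over as strings, so
`0.500` is indexed as written and re-indexing is deterministic). The
pairing of fields *within* an element of an object array is lost by
design — the text stays searchable, the structure does not. All flattened
values are concatenated in sorted-path order into a single catch-all field,
and the inverted index (postings with term frequencies, document lengths,
document frequencies) is built over that field only. Treating metadata as
one unstructured bag is a deliberate modeling choice: per-field weighting
is a different system, listed under limitations.

Unparseable inputs are counted and skipped, never fatal, because real
metadata dumps always contain a few malformed records; an import that
yields zero records, or two records with the same id, is fatal (silent
overwrites would corrupt evaluation downstream).

Tokenization approximates Unicode (UAX-29-style) word segmentation with a
regular expression: runs of letters/digits/marks form tokens; a single
medial apostrophe, full stop or comma does not split (`don't`, `3.14`,
`example.com`); hyphens and other punctuation do (`IL-6` → `il`, `6`).
Tokens are case-folded (not merely lowercased) so case-insensitivity holds
for one-way case pairs like ß/SS. No stemming and no index-time stopping:
stopword removal is a query-side operation here.

## Query processing and ranking

Preprocessing: lowercase → strip lead-in phrases (a packaged, editable
list of literal phrases matched with word boundaries; it is configuration,
not ground truth) → tokenize → drop stopwords (packaged standard English
list). The result is the baseline token bag. Expansion looks each baseline
token up in a TSV synonym table whose file order is canonical — a
reproducible stand-in for a live terminology service whose result order
would otherwise be an uncontrolled variable — takes the first
`max_terms = K` headings, concatenates all headings into one string, and
re-tokenizes it, so multiword headings contribute their word tokens rather
than phrases. Within the expansion bag duplicates are removed (first
occurrence kept): repeated words would silently multiply their effective
weight. Baseline tokens reappearing as synonyms are *not* removed from the
bag, keeping the two clauses independently additive.

Scoring is BM25 (`k1 = 1.2`, `b = 0.75`, non-negative smoothed
`idf = ln(1 + (N − df + 0.5)/(df + 0.5))` — the stock configuration of the
Lucene-family engines this reproduces) applied to each clause, combined as

    score(d) = baseline_weight · BM25(baseline, d)
             + mesh_weight · BM25(expansion, d)

over the union of documents matching at least one token of either clause.
This realizes "should" semantics: neither clause is required. The ratio
notation `a:b` always reads mesh:baseline in config and code; both
orientations occur in the field's reporting, so the orientation is explicit
rather than implied. Ties in score break by ascending document id —
engines break them nondeterministically, but byte-identical run files are
a requirement here. Scores print at 6 decimals in treceval format.

## Evaluation

Grades are 0/1/2 (not / partially / fully relevant). Gain is linear in the
grade with discount `1/log2(rank+1)`; exponential gain `2^g − 1` is
available behind a flag but linear is the default, matching the
treceval-family convention for this task. AP (and infAP) binarize at grade
≥ 1 by default, with a flag to require grade 2. Unjudged documents count as
non-relevant in the top-k metrics.

**infAP.** For sampled judgments, each sampled relevant document at rank k
contributes an estimate of P@k: `1/k` plus the pooled fraction of the k−1
documents above times the smoothed relevant fraction among *sampled*
documents above, counts weighted by 1/p of their stratum; the sum divides
by the number of sampled relevant documents. Smoothing uses eps = 1e-5
(exposed in the signature). When a query's pool is exhaustively judged at
rate 1 there is no sampling uncertainty and the implementation returns the
exact average precision over the pooled judgments — the estimator's eps→0
limit — rather than a value perturbed by the smoothing constant.

**infNDCG.** Per stratum, the count of grade-g documents among the sampled
is scaled by 1/p to estimate the stratum's true count, and the mean sampled
gain estimates the gain of pooled-but-unsampled documents. Estimated DCG
credits each ranked document with its judged gain, its stratum's mean gain
if pooled-unsampled, and 0 outside the pool (condition-on-pool convention).
Estimated ideal DCG fills ranks with the estimated number of grade-2 then
grade-1 documents, fractional remainders contributing proportionally at the
next rank. The ratio is clamped to [0, 1]. infNDCG evaluates the full
submitted list; NDCG@10 is reported separately. With all rates 1 and a
fully judged pool both estimators reduce exactly (to 1e-9) to AP and NDCG,
and the test suite enforces this reduction as the governing contract — the
exact estimator variant inside any particular organizer's scoring script is
not claimed.

Means over queries are unweighted arithmetic means. Queries missing from
the qrels are excluded with a warning; judged-but-empty queries report
zeros and are flagged.

## Synthetic collections

The generator emulates the *structure* of a dataset-retrieval benchmark,
not its content. Each latent concept has one query-side token and
`synonyms_per_concept` document-side forms, all registered in the emitted
synonym table. With probability `mismatch_rate` a concept is mismatched:
documents carry only its synonym forms, so baseline retrieval cannot see
it and expansion is the only route. Documents are `doc_concepts` concept
surface forms (1–3 occurrences each) plus `noise_tokens` noise words drawn
Zipf-like (exponent 1.1, vocabulary 200) so idf statistics are
nondegenerate, wrapped in a nested JSON record that exercises the
flattening rules. Query concept sets are sampled from a randomly chosen
document's concepts, guaranteeing at least one fully relevant document per
query. Grades follow deterministically from concept coverage:
grade 2 at coverage ≥ theta2 (default 0.99, i.e. all query concepts),
grade 1 at ≥ theta1 (default 0.5). Stratified judging is emulated by
pooling the top ranks of submitted runs ((depth, rate) defaults
(20, 1.0), (100, 0.5)), assigning each pooled document to the stratum of
its best rank, and sampling without replacement per stratum with
floor-plus-randomized-remainder so sample sizes are deterministic given
the seed.

Default study conditions: 500 documents, 10 queries, 20 concepts, 5
concepts per document, 3 query concepts, mismatch 0.8. The replicated
benefit study (`meshir.experiments`) runs 50 replicates per mismatch rate
in {0, 0.4, 0.8}; these sizes make each replicate sub-second while leaving
dozens of graded documents per query.

What the generator does **not** emulate: real metadata field schemas and
their sparsity, term-frequency distributions of natural language, semantic
(rather than surface-form) relevance, judge disagreement, and synonym
tables with irrelevant or ambiguous entries. Passing the synthetic study
therefore shows the machinery is correct and that expansion recovers
engineered mismatch; it does not predict effect sizes on any real
collection, where historical improvements are on the order of 10% rather
than the large gains synthetic mismatch produces.

## Numerical and design choices

- All randomness flows from explicit integer seeds (numpy `default_rng`);
  identical inputs give byte-identical outputs, which the tests check at
  the file level.
- The ranking, not the scores, is invariant under scaling both clause
  weights; tests assert rank equality and score proportionality.
- Degenerate inputs: empty query after preprocessing → empty ranked list
  with a warning; empty synonym table → baseline-only behavior; empty
  ideal gain → metric 0 (the 0/0 convention).
- The packaged ~200-token MeSH synonym table is a curated demonstration
  fixture for realistic examples; synthetic experiments always generate
  their own table.

## Known limitations

- Single catch-all field: no per-field boosting, filtering, or structured
  metadata exploitation.
- The tokenizer approximates UAX-29 with a regex; exotic segmentation
  cases (complex scripts, ZWJ sequences) may differ from a full
  implementation.
- No phrase matching: multiword headings are reduced to word bags.
- Synonym quality is taken as given; no filtering, disambiguation or
  statistical re-weighting of expansion terms.
- The index is held in memory and persisted as JSON; it targets
  desk-scale corpora (10^2–10^5 records), not production indexes.
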