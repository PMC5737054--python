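# meshir

Query expansion with Medical Subject Headings (MeSH) for biomedical
**dataset retrieval**: a self-contained toolkit that indexes JSON
dataset-metadata records, expands free-text queries with capped
controlled-vocabulary synonym lookups, ranks with weighted two-clause BM25,
writes treceval-format runs, and evaluates them with the graded and
inferred metrics used in TREC-style dataset-retrieval shared tasks.

It is written for information-retrieval researchers who want to study
vocabulary-mismatch compensation offline: every input a live experiment
needs — corpus, synonym table, queries, graded qrels, stratified-sampled
qrels — can be generated synthetically with known ground truth, so the
benefit of expansion is a measurable, tunable quantity rather than an
anecdote.

## The method

A raw query is lowercased, common lead-in phrases ("search for", "find",
...) are stripped by regular expression, and English stopwords are removed,
giving the *baseline query* `q_b`. Each baseline token is looked up in a
MeSH synonym table; the first *K* headings per token are concatenated and
re-tokenized into an *expansion bag* `q_m`. Documents are scored with two
optional ("should") clauses:

```
score(d) = w_b · BM25(q_b, d) + w_m · BM25(q_m, d)
```

with `BM25` using `k1 = 1.2`, `b = 0.75` and
`idf(t) = ln(1 + (N − df + 0.5)/(df + 0.5))`. Neither clause is required:
a document matching only synonyms is still retrieved, and the weight ratio
`w_m : w_b` (e.g. 1:5) keeps poorly matched synonyms from overwhelming the
original terms. Top-1000 lists per query are written in treceval run
format.

Evaluation implements **P@10** (counting grade ≥ 1 or only grade 2),
**NDCG@10**, and the inferred estimators **infAP** and **infNDCG** for
stratified-sampled judgments, where relevant-document counts observed in a
judged sample are scaled by the inverse sampling rate 1/p of their stratum.
Named run presets `OHSU-1` … `OHSU-5` reproduce the structure of the five
standard submission configurations (baseline; 5 terms at 1:1, 1:2, 1:5;
20 terms at 1:2).

## Worked example

Generate a 500-document synthetic collection with heavy vocabulary
mismatch (80% of concepts appear in documents only under synonym forms),
index it, and compare the unexpanded baseline against 5-term 1:5 expansion:

```
$ meshir gen --out coll --seed 7
$ meshir index --corpus coll/corpus --out idx.json
indexed 500 docs (0 skipped) -> idx.json
$ meshir search --index idx.json --queries coll/queries.tsv \
    --synonyms coll/synonyms.tsv --preset OHSU-1 --run-id OHSU-1 --out base.txt
$ meshir search --index idx.json --queries coll/queries.tsv \
    --synonyms coll/synonyms.tsv --preset OHSU-4 --run-id OHSU-4 --out exp.txt
$ meshir sample --qrels coll/qrels.txt --runs base.txt --runs exp.txt \
    --seed 8 --out sq.txt
$ meshir eval --run exp.txt --qrels coll/qrels.txt --sampled-qrels sq.txt
infAP   0.9739
infNDCG 0.9648
NDCG@10 0.9631
P@10+partial    1.0000
P@10-partial    0.4300
```

The same evaluation of `base.txt` gives infNDCG 0.6819 and NDCG@10 0.2829:
with most query concepts hidden behind synonyms, the baseline finds
relevant documents only through their few surface-matching terms, while the
expanded query recovers them through the synonym clause. Run files look
like

```
q1 Q0 d460 1 20.131354 OHSU-4
q1 Q0 d331 2 18.531084 OHSU-4
```

and `meshir sweep` evaluates a full synonym-cap × weight-ratio grid with a
baseline column, per-query deltas and the best cell per query.

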