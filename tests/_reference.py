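"""Naive reference implementations used as independent oracles in tests.

Everything here is written as a direct transcription of the metric and
scoring definitions — plain loops over plain data structures — and stays
independent of the package's own code paths.
"""

from __future__ import annotations

import math


def ref_precision_at_k(ranked_docs, grade_of, k, min_grade):
    hits = 0
    for i, doc in enumerate(ranked_docs[:k], start=1):
        if grade_of.get(doc, 0) >= min_grade:
            hits += 1
    return hits / k


def ref_average_precision(ranked_docs, grade_of, min_grade):
    r_total = sum(1 for g in grade_of.values() if g >= min_grade)
    if r_total == 0:
        return 0.0
    hits = 0
    acc = 0.0
    for i, doc in enumerate(ranked_docs, start=1):
        if grade_of.get(doc, 0) >= min_grade:
            hits += 1
            acc += hits / i
    return acc / r_total


def ref_ndcg_at_k(ranked_docs, grade_of, k=None):
    docs = ranked_docs if k is None else ranked_docs[:k]
    dcg = sum(grade_of.get(d, 0) / math.log2(i + 1)
              for i, d in enumerate(docs, start=1))
    ideal = sorted(grade_of.values(), reverse=True)
    if k is not None:
        ideal = ideal[:k]
    idcg = sum(g / math.log2(i + 1) for i, g in enumerate(ideal, start=1))
    return dcg / idcg if idcg > 0 else 0.0


def ref_inf_ap(ranked_docs, pool, rates, grades, min_grade=1, eps=1e-5):
    """Stated inferred-AP estimator, transcribed term by term.

    pool: doc -> stratum; rates: stratum -> p; grades: sampled doc -> grade.
    """
    r_s = sum(1 for g in grades.values() if g >= min_grade)
    if r_s == 0:
        return 0.0
    total = 0.0
    for idx, doc in enumerate(ranked_docs):
        k = idx + 1
        if doc not in grades or grades[doc] < min_grade:
            continue
        if k == 1:
            total += 1.0
            continue
        above = ranked_docs[:idx]
        pooled_above = sum(1 for d in above if d in pool)
        rel = sum(1.0 / rates[pool[d]] for d in above
                  if d in grades and grades[d] >= min_grade)
        nonrel = sum(1.0 / rates[pool[d]] for d in above
                     if d in grades and grades[d] < min_grade)
        total += (1.0 / k + ((k - 1) / k) * (pooled_above / (k - 1))
                  * ((rel + eps) / (rel + nonrel + 2 * eps)))
    return total / r_s


def ref_bm25(doc_tokens_by_id, bag, doc_id, k1=1.2, b=0.75):
    """Exhaustive BM25 from raw token lists, no index involved."""
    n = len(doc_tokens_by_id)
    avg = sum(len(t) for t in doc_tokens_by_id.values()) / n
    tokens = doc_tokens_by_id[doc_id]
    score = 0.0
    for term in bag:
        tf = tokens.count(term)
        if tf == 0:
            continue
        df = sum(1 for t in doc_tokens_by_id.values() if term in t)
        idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
        score += idf * tf * (k1 + 1.0) / (tf + k1 * (1 - b + b * len(tokens) / avg))
    return score


def ref_rank_all(doc_tokens_by_id, baseline_bag, expansion_bag,
                 w_base, w_mesh, top_n):
    """Score every document exhaustively and rank like the search contract."""
    scored = []
    for doc_id in doc_tokens_by_id:
        s = w_base * ref_bm25(doc_tokens_by_id, baseline_bag, doc_id)
        if expansion_bag:
            s += w_mesh * ref_bm25(doc_tokens_by_id, expansion_bag, doc_id)
        if s > 0.0:
            scored.append((-s, doc_id))
    scored.sort()
    return [(doc_id, -neg) for neg, doc_id in scored[:top_n]]
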