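"""Graded and inferred retrieval metrics over TREC-style qrels.

Evaluates ranked runs against graded relevance judgments (0 = not, 1 =
partially, 2 = fully relevant) with the five-metric set used for shared-task
dataset retrieval: P@10 counting partial matches, P@10 counting only full
matches, NDCG@10, and the inferred estimators infAP and infNDCG for the
common situation where only a stratified random sample of the judging pool
was actually assessed.

Inferred metrics treat the judged sample as a survey of the pool: counts of
relevant documents observed in a stratum are scaled up by the inverse
sampling rate 1/p, and expected precision above a rank is estimated from the
sampled documents seen there.  When every stratum is exhaustively judged
(all rates 1), both estimators reduce exactly to their deterministic
counterparts.

Gains are linear in the grade with a 1/log2(rank+1) discount (rank 1
undiscounted); the exponential 2^g - 1 gain used by some web-search
evaluations is available via ``gain="exponential"``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .retrieval import RankedList, read_run

logger = logging.getLogger(__name__)

__all__ = [
    "Qrels",
    "SampledQrels",
    "MetricReport",
    "SweepGrid",
    "parse_qrels",
    "write_qrels",
    "parse_sampled_qrels",
    "write_sampled_qrels",
    "precision_at_k",
    "ndcg_at_k",
    "average_precision",
    "inf_ap",
    "inf_ndcg",
    "evaluate_run",
    "sweep",
    "METRIC_KEYS",
]

GRADES = (0, 1, 2)
DEFAULT_EPS = 1e-5


def _gain(grade: int, gain: str) -> float:
    if gain == "linear":
        return float(grade)
    if gain == "exponential":
        return float(2 ** grade - 1)
    raise ValueError(f"unknown gain function {gain!r}")


def _disc(rank: int) -> float:
    return 1.0 / math.log2(rank + 1)


# ---------------------------------------------------------------------------
# Judgment containers and file dialects
# ---------------------------------------------------------------------------

@dataclass
class Qrels:
    """Graded judgments: ``(qid, doc_id) -> grade`` in {0, 1, 2}.

    An absent pair means the document was never judged and is treated as
    grade 0 by the top-k metrics.
    """

    grades: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        bad = {g for g in self.grades.values() if g not in GRADES}
        if bad:
            raise ValueError(f"grades must be in {GRADES}, got {sorted(bad)}")

    def grade(self, qid: str, doc_id: str) -> int:
        return self.grades.get((qid, doc_id), 0)

    def qids(self) -> list[str]:
        return sorted({q for q, _ in self.grades})

    def query_grades(self, qid: str) -> list[int]:
        return [g for (q, _), g in self.grades.items() if q == qid]

    def n_relevant(self, qid: str, min_grade: int = 1) -> int:
        return sum(1 for (q, _), g in self.grades.items()
                   if q == qid and g >= min_grade)


@dataclass
class SampledQrels:
    """Stratified-sampled judgments over a pooled candidate set.

    ``pool`` assigns every pooled document to a stratum, ``rates`` gives the
    per-query sampling probability of each stratum, and ``grades`` holds
    judgments for the sampled documents only.  Documents in the pool but not
    sampled were eligible for judging yet never assessed; documents outside
    the pool were never candidates.
    """

    pool: dict[tuple[str, str], str]
    rates: dict[tuple[str, str], float]
    grades: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for key, g in self.grades.items():
            if g not in GRADES:
                raise ValueError(f"grade {g} for {key} not in {GRADES}")
            if key not in self.pool:
                raise ValueError(f"graded doc {key} missing from pool")
        for (qid, doc_id), stratum in self.pool.items():
            rate = self.rates.get((qid, stratum))
            if rate is None:
                raise ValueError(f"no sampling rate for query {qid} "
                                 f"stratum {stratum}")
            if not (0.0 < rate <= 1.0):
                raise ValueError(f"rate {rate} for ({qid}, {stratum}) "
                                 "outside (0, 1]")

    def qids(self) -> list[str]:
        return sorted({q for q, _ in self.pool})

    def fully_judged(self, qid: str) -> bool:
        """True when every pooled doc of ``qid`` is judged at rate 1."""
        for (q, doc_id), stratum in self.pool.items():
            if q != qid:
                continue
            if self.rates[(q, stratum)] != 1.0 or (q, doc_id) not in self.grades:
                return False
        return True

    @classmethod
    def from_full_qrels(cls, qrels: Qrels) -> "SampledQrels":
        """View full judgments as a single exhaustively-sampled stratum."""
        pool = {key: "1" for key in qrels.grades}
        rates = {(qid, "1"): 1.0 for qid in qrels.qids()}
        return cls(pool=pool, rates=rates, grades=dict(qrels.grades))


def parse_qrels(path: str | Path) -> Qrels:
    """Parse standard 4-column qrels: ``qid 0 doc_id grade``."""
    grades: dict[tuple[str, str], int] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            qid, _, doc_id, grade = parts
            try:
                g = int(grade)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer grade "
                                 f"{grade!r}") from None
            if g not in GRADES:
                raise ValueError(f"{path}:{lineno}: grade {g} not in 0/1/2")
            grades[(qid, doc_id)] = g
    return Qrels(grades=grades)


def write_qrels(qrels: Qrels, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for (qid, doc_id), g in sorted(qrels.grades.items()):
            fh.write(f"{qid} 0 {doc_id} {g}\n")


def parse_sampled_qrels(path: str | Path) -> SampledQrels:
    """Parse the stratified-sample qrels dialect.

    Header lines ``#rate <qid> <stratum_id> <p>`` give per-stratum sampling
    rates.  Data lines are ``qid stratum_id doc_id grade`` where grade is
    0/1/2 for a sampled (judged) document or ``-`` for a document that is in
    the pool but was not drawn into the judged sample.
    """
    pool: dict[tuple[str, str], str] = {}
    rates: dict[tuple[str, str], float] = {}
    grades: dict[tuple[str, str], int] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if parts[0] == "#rate":
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: #rate needs "
                                     "<qid> <stratum> <p>")
                try:
                    p = float(parts[3])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-numeric rate "
                                     f"{parts[3]!r}") from None
                rates[(parts[1], parts[2])] = p
                continue
            if line.startswith("#"):
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            qid, stratum, doc_id, grade = parts
            pool[(qid, doc_id)] = stratum
            if grade != "-":
                try:
                    g = int(grade)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: grade must be 0/1/2 "
                                     f"or '-', got {grade!r}") from None
                grades[(qid, doc_id)] = g
    try:
        return SampledQrels(pool=pool, rates=rates, grades=grades)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_sampled_qrels(sq: SampledQrels, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for (qid, stratum), p in sorted(sq.rates.items()):
            fh.write(f"#rate {qid} {stratum} {p:g}\n")
        for (qid, doc_id), stratum in sorted(sq.pool.items()):
            g = sq.grades.get((qid, doc_id))
            fh.write(f"{qid} {stratum} {doc_id} {'-' if g is None else g}\n")


# ---------------------------------------------------------------------------
# Deterministic metrics
# ---------------------------------------------------------------------------

def precision_at_k(ranked: RankedList, qrels: Qrels, k: int,
                   min_grade: int = 1) -> float:
    """Fraction of the top ``k`` ranks holding a grade >= ``min_grade`` doc.

    Unjudged documents count as non-relevant and rankings shorter than ``k``
    are implicitly padded with non-relevant documents.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = sum(1 for doc_id, _, rank in ranked.entries
               if rank <= k and qrels.grade(ranked.qid, doc_id) >= min_grade)
    return hits / k


def ndcg_at_k(ranked: RankedList, qrels: Qrels, k: int | None = 10,
              gain: str = "linear") -> float:
    """Normalized discounted cumulative gain at cutoff ``k``.

    The ideal DCG comes from all graded documents of the query sorted by
    grade descending.  A query with no positively graded documents scores 0
    (the 0/0 convention).  ``k=None`` evaluates the full ranked list.
    """
    if k is not None and k < 1:
        raise ValueError("k must be >= 1 or None")
    dcg = 0.0
    for doc_id, _, rank in ranked.entries:
        if k is not None and rank > k:
            continue
        dcg += _gain(qrels.grade(ranked.qid, doc_id), gain) * _disc(rank)
    ideal_grades = sorted(qrels.query_grades(ranked.qid), reverse=True)
    if k is not None:
        ideal_grades = ideal_grades[:k]
    idcg = sum(_gain(g, gain) * _disc(i)
               for i, g in enumerate(ideal_grades, start=1))
    return dcg / idcg if idcg > 0 else 0.0


def average_precision(ranked: RankedList, qrels: Qrels,
                      min_grade: int = 1) -> float:
    """Mean of precision at each relevant rank, over all relevant docs.

    Binarizes grades at ``min_grade`` (the default counts partially relevant
    documents as relevant).  Relevant documents never retrieved contribute 0
    through the denominator R.  R = 0 scores 0.
    """
    r_total = qrels.n_relevant(ranked.qid, min_grade)
    if r_total == 0:
        return 0.0
    hits = 0
    total = 0.0
    for doc_id, _, rank in ranked.entries:
        if qrels.grade(ranked.qid, doc_id) >= min_grade:
            hits += 1
            total += hits / rank
    return total / r_total


# ---------------------------------------------------------------------------
# Inferred metrics over sampled judgments
# ---------------------------------------------------------------------------

def _query_view(sq: SampledQrels, qid: str):
    pool = {d: s for (q, d), s in sq.pool.items() if q == qid}
    rates = {s: p for (q, s), p in sq.rates.items() if q == qid}
    grades = {d: g for (q, d), g in sq.grades.items() if q == qid}
    return pool, rates, grades


def inf_ap(ranked: RankedList, sq: SampledQrels, min_grade: int = 1,
           eps: float = DEFAULT_EPS) -> float:
    """Inferred average precision over stratified-sampled judgments.

    Each sampled relevant document at rank k contributes an estimate of
    P@k built from the documents ranked above it: the chance a doc above is
    in the pool, times the smoothed relevant fraction among sampled docs
    above, with sampled counts weighted by 1/p of their stratum.  The sum is
    divided by the number of sampled relevant documents.  The rank-1 term
    contributes exactly 1.

    When the pool is exhaustively judged (all rates 1) the estimator has no
    sampling uncertainty and the exact average precision over the pooled
    judgments is returned, without smoothing.
    """
    qid = ranked.qid
    pool, rates, grades = _query_view(sq, qid)
    if sq.fully_judged(qid):
        return average_precision(ranked, Qrels(
            grades={(qid, d): g for d, g in grades.items()}), min_grade)
    r_sampled = sum(1 for g in grades.values() if g >= min_grade)
    if r_sampled == 0:
        return 0.0
    total = 0.0
    above: list[str] = []
    for doc_id, _, rank in ranked.entries:
        if doc_id in grades and grades[doc_id] >= min_grade:
            if rank == 1:
                total += 1.0
            else:
                k = rank
                pooled_above = sum(1 for d in above if d in pool)
                rel_above = sum(1.0 / rates[pool[d]] for d in above
                                if d in grades and grades[d] >= min_grade)
                nonrel_above = sum(1.0 / rates[pool[d]] for d in above
                                   if d in grades and grades[d] < min_grade)
                p_est = (1.0 / k
                         + ((k - 1) / k)
                         * (pooled_above / (k - 1))
                         * ((rel_above + eps)
                            / (rel_above + nonrel_above + 2 * eps)))
                total += p_est
        above.append(doc_id)
    return total / r_sampled


def inf_ndcg(ranked: RankedList, sq: SampledQrels,
             gain: str = "linear") -> float:
    """Inferred NDCG over the full ranked list with stratified sampling.

    The DCG estimate credits each ranked document with its judged gain, the
    mean sampled gain of its stratum when pooled but unsampled, and 0 when
    outside the pool.  The ideal DCG estimate fills ranks with the
    scaled-up (1/p) estimated counts of fully then partially relevant
    documents, fractional remainders contributing proportionally at the
    next rank.  The ratio is clamped to [0, 1]; an empty estimated ideal
    scores 0.
    """
    qid = ranked.qid
    pool, rates, grades = _query_view(sq, qid)
    # per-stratum estimated grade counts and mean sampled gain
    strata = sorted(set(pool.values()))
    m_hat: dict[str, dict[int, float]] = {}
    g_hat: dict[str, float] = {}
    for s in strata:
        sampled = [grades[d] for d, st in pool.items()
                   if st == s and d in grades]
        p = rates[s]
        m_hat[s] = {g: sum(1 for x in sampled if x == g) / p for g in GRADES}
        g_hat[s] = (sum(_gain(x, gain) for x in sampled) / len(sampled)
                    if sampled else 0.0)
    dcg = 0.0
    for doc_id, _, rank in ranked.entries:
        if doc_id in grades:
            contrib = _gain(grades[doc_id], gain)
        elif doc_id in pool:
            contrib = g_hat[pool[doc_id]]
        else:
            contrib = 0.0
        dcg += contrib * _disc(rank)
    idcg = 0.0
    rank = 1
    for grade in (2, 1):
        count = sum(m_hat[s][grade] for s in strata)
        whole = int(math.floor(count))
        for _ in range(whole):
            idcg += _gain(grade, gain) * _disc(rank)
            rank += 1
        frac = count - whole
        if frac > 1e-12:
            idcg += frac * _gain(grade, gain) * _disc(rank)
            rank += 1
    if idcg <= 0.0:
        return 0.0
    return min(max(dcg / idcg, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Run-level evaluation
# ---------------------------------------------------------------------------

METRIC_KEYS = ("infAP", "infNDCG", "NDCG@10", "P@10+partial", "P@10-partial")


@dataclass
class MetricReport:
    """Per-query metric values plus unweighted arithmetic means."""

    per_query: dict[str, dict[str, float]]
    means: dict[str, float]
    unjudged_qids: list[str] = field(default_factory=list)
    excluded_qids: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        keys = list(next(iter(self.per_query.values())).keys()) \
            if self.per_query else list(METRIC_KEYS)
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("qid\t" + "\t".join(keys) + "\n")
            for qid in sorted(self.per_query):
                row = self.per_query[qid]
                fh.write(qid + "\t"
                         + "\t".join(f"{row[k]:.4f}" for k in keys) + "\n")
            fh.write("MEAN\t"
                     + "\t".join(f"{self.means[k]:.4f}" for k in keys) + "\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_query": self.per_query,
            "means": self.means,
            "unjudged_qids": self.unjudged_qids,
            "excluded_qids": self.excluded_qids,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True),
                              encoding="utf-8")


def evaluate_run(run: str | Path | Mapping[str, RankedList], qrels: Qrels,
                 sampled_qrels: SampledQrels | None = None, k: int = 10,
                 min_grade: int = 1, eps: float = DEFAULT_EPS,
                 gain: str = "linear") -> MetricReport:
    """Score a run with the five-metric challenge set.

    ``run`` is a treceval run file path or a mapping of ranked lists.  Top-k
    metrics (P@k both variants, NDCG@k) use the full graded qrels; the
    inferred metrics use ``sampled_qrels``, falling back to an
    exhaustively-sampled view of ``qrels`` when none is given.  Queries
    absent from the qrels are excluded from the means with a warning;
    queries with no judged documents are reported as zeros and flagged.
    """
    lists = read_run(run) if isinstance(run, (str, Path)) else dict(run)
    if sampled_qrels is None:
        sampled_qrels = SampledQrels.from_full_qrels(qrels)
    judged_qids = set(qrels.qids()) | set(sampled_qrels.qids())
    per_query: dict[str, dict[str, float]] = {}
    unjudged: list[str] = []
    excluded: list[str] = []
    for qid in lists:
        if qid not in judged_qids:
            excluded.append(qid)
    if excluded:
        logger.warning("%d run queries absent from qrels, excluded: %s",
                       len(excluded), ", ".join(sorted(excluded)))
    for qid, rl in lists.items():
        if qid in excluded:
            continue
        if not qrels.query_grades(qid) and not any(
                q == qid for q, _ in sampled_qrels.pool):
            unjudged.append(qid)
            per_query[qid] = {key.replace("@10", f"@{k}"): 0.0
                              for key in METRIC_KEYS}
            continue
        per_query[qid] = {
            "infAP": inf_ap(rl, sampled_qrels, min_grade=min_grade, eps=eps),
            "infNDCG": inf_ndcg(rl, sampled_qrels, gain=gain),
            f"NDCG@{k}": ndcg_at_k(rl, qrels, k=k, gain=gain),
            f"P@{k}+partial": precision_at_k(rl, qrels, k=k, min_grade=1),
            f"P@{k}-partial": precision_at_k(rl, qrels, k=k, min_grade=2),
        }
    if unjudged:
        logger.warning("queries with no judged docs reported as zeros: %s",
                       ", ".join(sorted(unjudged)))
    if not per_query:
        raise ValueError("no evaluable queries in run")
    keys = list(next(iter(per_query.values())).keys())
    means = {key: sum(row[key] for row in per_query.values()) / len(per_query)
             for key in keys}
    return MetricReport(per_query=per_query, means=means,
                        unjudged_qids=sorted(unjudged),
                        excluded_qids=sorted(excluded))


# ---------------------------------------------------------------------------
# Parameter sweep: synonym cap x weight ratio
# ---------------------------------------------------------------------------

@dataclass
class SweepGrid:
    """Terms-by-weights grid of metric reports plus per-query best cells."""

    ks: list[int]
    ratios: list[str]
    cells: dict[tuple[int, str], MetricReport]
    baseline: MetricReport
    best_per_query: dict[str, tuple[int, str, float]]
    deltas: dict[tuple[int, str], dict[str, float]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ks": self.ks,
            "ratios": self.ratios,
            "cells": {f"{k}|{r}": rep.means for (k, r), rep in self.cells.items()},
            "baseline_means": self.baseline.means,
            "best_per_query": {q: {"max_terms": k, "ratio": r, "infNDCG": v}
                               for q, (k, r, v) in self.best_per_query.items()},
            "deltas_vs_baseline": {f"{k}|{r}": d
                                   for (k, r), d in self.deltas.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True),
                              encoding="utf-8")


def sweep(index, queries: Sequence[tuple[str, str]], table, ks: Sequence[int],
          ratios: Sequence[str], qrels: Qrels,
          sampled_qrels: SampledQrels | None = None, top_n: int = 1000,
          k: int = 10, min_grade: int = 1, eps: float = DEFAULT_EPS,
          gain: str = "linear") -> SweepGrid:
    """Evaluate every (max_terms, ratio) cell with identical preprocessing.

    A baseline column (expansion off) is always evaluated alongside the
    grid.  ``best_per_query`` picks, per query, the grid cell with maximal
    infNDCG; ties prefer fewer synonyms, then the heavier-baseline ratio.
    ``deltas`` holds each cell's per-query infNDCG minus the baseline's.
    """
    from .expansion import ExpansionConfig, parse_ratio
    from .retrieval import build_query, search
    if not ks or not ratios:
        raise ValueError("ks and ratios must be non-empty")

    def run_cell(max_terms: int, ratio: str | None) -> MetricReport:
        if max_terms == 0:
            cfg = ExpansionConfig(max_terms=0, mesh_weight=1.0,
                                  baseline_weight=1.0)
        else:
            mesh_w, base_w = parse_ratio(ratio)
            cfg = ExpansionConfig(max_terms=max_terms, mesh_weight=mesh_w,
                                  baseline_weight=base_w)
        lists = {qid: search(index, build_query(qid, text, table, cfg),
                             top_n=top_n)
                 for qid, text in queries}
        try:
            return evaluate_run(lists, qrels, sampled_qrels, k=k,
                                min_grade=min_grade, eps=eps, gain=gain)
        except ValueError as exc:
            raise ValueError(f"cell (max_terms={max_terms}, "
                             f"ratio={ratio}): {exc}") from exc

    baseline = run_cell(0, None)
    cells = {(kk, rr): run_cell(kk, rr) for kk in ks for rr in ratios}
    deltas = {
        cell: {qid: rep.per_query[qid]["infNDCG"]
               - baseline.per_query[qid]["infNDCG"]
               for qid in rep.per_query if qid in baseline.per_query}
        for cell, rep in cells.items()
    }

    def base_heaviness(ratio: str) -> float:
        mesh_w, base_w = parse_ratio(ratio)
        return base_w / mesh_w

    best: dict[str, tuple[int, str, float]] = {}
    for qid in baseline.per_query:
        candidates = [(rep.per_query[qid]["infNDCG"], kk, rr)
                      for (kk, rr), rep in cells.items()
                      if qid in rep.per_query]
        if not candidates:
            continue
        candidates.sort(key=lambda t: (-t[0], t[1], -base_heaviness(t[2])))
        value, kk, rr = candidates[0]
        best[qid] = (kk, rr, value)
    return SweepGrid(ks=list(ks), ratios=list(ratios), cells=cells,
                     baseline=baseline, best_per_query=best, deltas=deltas)
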