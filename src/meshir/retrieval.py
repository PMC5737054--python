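"""Query preprocessing, weighted two-clause BM25 ranking, and TREC run I/O.

A raw query is lowercased, common lead-in phrases ("search for", "find ...")
are stripped with regular expressions, and English stopwords are dropped,
yielding the *baseline query*.  Retrieval scores every candidate document as

    score(d) = w_base * BM25(baseline bag, d) + w_mesh * BM25(expansion bag, d)

i.e. two optional ("should") clauses: neither clause is required, a match on
either raises the score, and the boost ratio controls how much the expansion
clause counts relative to the baseline.  BM25 uses k1 = 1.2, b = 0.75 and the
non-negative smoothed idf ln(1 + (N - df + 0.5)/(df + 0.5)), the stock
configuration of the Lucene-family engines this module mirrors.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import InvertedIndex, tokenize
from .expansion import ExpansionConfig, SynonymTable, build_expansion_bag

logger = logging.getLogger(__name__)

__all__ = [
    "StructuredQuery",
    "RankedList",
    "load_stopwords",
    "load_phrase_patterns",
    "default_stopwords",
    "default_phrase_patterns",
    "preprocess",
    "build_query",
    "bm25_score",
    "search",
    "write_run",
    "read_run",
    "read_queries",
]

K1 = 1.2
B = 0.75


# ---------------------------------------------------------------------------
# Preprocessing fixtures
# ---------------------------------------------------------------------------

def _read_fixture(name: str) -> list[str]:
    text = resources.files("meshir.data").joinpath(name).read_text("utf-8")
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Stopword set: one word per line, ``#`` comments ignored."""
    if path is None:
        return frozenset(_read_fixture("stopwords_en.txt"))
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(ln.strip().lower() for ln in lines
                     if ln.strip() and not ln.startswith("#"))


def load_phrase_patterns(path: str | Path | None = None) -> list[re.Pattern]:
    """Compile the lead-in phrase removal list into word-bounded regexes.

    Each line of the fixture is a literal phrase ("search for", "datasets
    of", ...) removed from the lowercased query before tokenization.  The
    list is configuration, not hard-coded truth; pass ``path`` to use a
    custom one.
    """
    if path is None:
        phrases = _read_fixture("phrase_patterns.txt")
    else:
        phrases = [ln.strip() for ln in
                   Path(path).read_text(encoding="utf-8").splitlines()
                   if ln.strip() and not ln.startswith("#")]
    # longest first so "datasets of" wins over "datasets"
    phrases.sort(key=len, reverse=True)
    return [re.compile(r"\b" + re.escape(p.lower()) + r"\b") for p in phrases]


def default_stopwords() -> frozenset[str]:
    return load_stopwords(None)


def default_phrase_patterns() -> list[re.Pattern]:
    return load_phrase_patterns(None)


def preprocess(raw_query: str,
               stop_list: frozenset[str] | set[str] | None = None,
               phrase_patterns: Sequence[re.Pattern] | None = None) -> list[str]:
    """Raw query -> baseline token list.

    Pipeline: lowercase, remove lead-in phrases, tokenize with the index
    tokenizer, drop stopword tokens; token order is preserved.  An
    all-stopword query legitimately yields an empty list (the caller flags
    it and returns an empty ranking).
    """
    if stop_list is None:
        stop_list = default_stopwords()
    if phrase_patterns is None:
        phrase_patterns = default_phrase_patterns()
    text = raw_query.lower()
    for pat in phrase_patterns:
        text = pat.sub(" ", text)
    return [t for t in tokenize(text) if t not in stop_list]


# ---------------------------------------------------------------------------
# Structured queries and ranked lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructuredQuery:
    """Baseline token bag + expansion token bag + clause weights."""

    qid: str
    baseline_tokens: tuple[str, ...]
    expansion_tokens: tuple[str, ...]
    config: ExpansionConfig


@dataclass
class RankedList:
    """Ranked retrieval result: ``(doc_id, score, rank)`` with rank from 1."""

    qid: str
    entries: list[tuple[str, float, int]] = field(default_factory=list)

    def doc_ids(self) -> list[str]:
        return [d for d, _, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def build_query(qid: str, raw_query: str, table: SynonymTable,
                config: ExpansionConfig,
                stop_list: frozenset[str] | None = None,
                phrase_patterns: Sequence[re.Pattern] | None = None) -> StructuredQuery:
    """Preprocess a raw query and attach its MeSH expansion bag."""
    baseline = preprocess(raw_query, stop_list, phrase_patterns)
    expansion: list[str] = []
    if config.max_terms > 0:
        expansion = build_expansion_bag(baseline, table, config.max_terms)
    return StructuredQuery(qid=qid, baseline_tokens=tuple(baseline),
                           expansion_tokens=tuple(expansion), config=config)


# ---------------------------------------------------------------------------
# BM25 scoring and search
# ---------------------------------------------------------------------------

def _idf(index: InvertedIndex, term: str) -> float:
    df = index.df(term)
    if df == 0:
        return 0.0
    n = index.n_docs
    return math.log(1.0 + (n - df + 0.5) / (df + 0.5))


def bm25_score(index: InvertedIndex, bag: Iterable[str], doc_id: str) -> float:
    """BM25 score of one document for a token bag (k1=1.2, b=0.75).

    Terms absent from the collection contribute 0; an empty bag scores 0.
    """
    if doc_id not in index.doc_len:
        raise KeyError(f"unknown doc_id {doc_id!r}")
    dl = index.doc_len[doc_id]
    avg = index.avg_len
    score = 0.0
    for term in bag:
        tf = index.tf(term, doc_id)
        if tf == 0:
            continue
        norm = K1 * (1.0 - B + B * (dl / avg if avg > 0 else 0.0))
        score += _idf(index, term) * tf * (K1 + 1.0) / (tf + norm)
    return score


def search(index: InvertedIndex, query: StructuredQuery,
           top_n: int = 1000) -> RankedList:
    """Rank documents for a two-clause structured query.

    Candidates are documents matching at least one token of either clause
    (should-semantics: neither clause is required).  Documents with positive
    combined score are sorted by score descending, ties broken by ascending
    doc id for reproducible output, and truncated to ``top_n``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if not query.baseline_tokens:
        logger.warning("query %s is empty after preprocessing; "
                       "returning no results", query.qid)
        return RankedList(qid=query.qid)
    cfg = query.config
    candidates: set[str] = set()
    for term in set(query.baseline_tokens) | set(query.expansion_tokens):
        candidates.update(d for d, _ in index.postings.get(term, ()))
    scored: list[tuple[float, str]] = []
    for doc_id in candidates:
        s = cfg.baseline_weight * bm25_score(index, query.baseline_tokens, doc_id)
        if query.expansion_tokens:
            s += cfg.mesh_weight * bm25_score(index, query.expansion_tokens, doc_id)
        if s > 0.0:
            scored.append((s, doc_id))
    scored.sort(key=lambda pair: (-pair[0], pair[1]))
    entries = [(doc_id, score, rank)
               for rank, (score, doc_id) in enumerate(scored[:top_n], start=1)]
    return RankedList(qid=query.qid, entries=entries)


# ---------------------------------------------------------------------------
# TREC run files and query files
# ---------------------------------------------------------------------------

def write_run(lists: Sequence[RankedList], run_id: str,
              path: str | Path) -> None:
    """Write ranked lists in the 6-column treceval run format.

    Lines are ``qid Q0 doc_id rank score run_id`` with scores at fixed
    6-decimal precision; queries appear in input order and a query with an
    empty ranking contributes no lines.
    """
    if not run_id or any(c.isspace() for c in run_id):
        raise ValueError("run_id must be non-empty and whitespace-free")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for rl in lists:
            for doc_id, score, rank in rl.entries:
                fh.write(f"{rl.qid} Q0 {doc_id} {rank} {score:.6f} {run_id}\n")


def read_run(path: str | Path) -> dict[str, RankedList]:
    """Parse a treceval run file into per-query ranked lists.

    Entries are ordered by the rank column; duplicate documents within a
    query are rejected.
    """
    per_query: dict[str, list[tuple[int, str, float]]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, "
                                 f"got {len(parts)}")
            qid, _, doc_id, rank, score, _ = parts
            per_query.setdefault(qid, []).append((int(rank), doc_id, float(score)))
    out: dict[str, RankedList] = {}
    for qid, rows in per_query.items():
        rows.sort()
        docs = [d for _, d, _ in rows]
        if len(set(docs)) != len(docs):
            raise ValueError(f"duplicate doc_ids for query {qid} in {path}")
        out[qid] = RankedList(qid=qid, entries=[(d, s, r) for r, d, s in rows])
    return out


def read_queries(path: str | Path) -> list[tuple[str, str]]:
    """Read a ``qid<TAB>query text`` file, preserving order."""
    out: list[tuple[str, str]] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if "\t" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'qid<TAB>text'")
            qid, text = line.split("\t", 1)
            out.append((qid.strip(), text.strip()))
    return out
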