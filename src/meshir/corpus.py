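"""Corpus ingestion and inverted indexing for JSON dataset-metadata records.

Dataset-discovery repositories exchange metadata as deeply nested JSON whose
schema varies between source archives.  This module flattens each record into
dot-separated ``path -> text`` pairs (list indices dropped, sibling values
space-joined), concatenates everything into a single catch-all searchable
field, and builds a classic inverted index (postings, document lengths,
collection statistics) over the catch-all text.  Treating the metadata as one
unstructured text field deliberately discards field structure: relationships
inside nested objects are lost, but every value remains searchable.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "MetadataRecord",
    "Corpus",
    "InvertedIndex",
    "flatten_record",
    "tokenize",
    "load_corpus",
    "build_index",
    "CorpusError",
]


class CorpusError(RuntimeError):
    """Fatal corpus-level problem (missing path, empty corpus, id collision)."""


# ---------------------------------------------------------------------------
# Record flattening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetadataRecord:
    """One dataset's metadata flattened to ``path -> text``.

    ``catchall`` is the space-joined concatenation of all field values in
    sorted-path order; it is the only text the index sees.
    """

    doc_id: str
    fields: dict[str, str]
    catchall: str


@dataclass
class Corpus:
    records: list[MetadataRecord]
    n_skipped: int = 0

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.records)


def _render_scalar(value: Any) -> str:
    # json loaded with parse_int=str/parse_float=str keeps the source lexical
    # form; python-native numbers from API callers are rendered canonically.
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _walk(node: Any, path: str, out: dict[str, list[str]]) -> None:
    if isinstance(node, Mapping):
        for key, child in node.items():
            sub = f"{path}.{key}" if path else str(key)
            _walk(child, sub, out)
    elif isinstance(node, (list, tuple)):
        # list indices dropped: elements merge under the parent path
        for child in node:
            _walk(child, path, out)
    else:
        text = _render_scalar(node)
        if path:
            out.setdefault(path, []).append(text)


def flatten_record(raw: Mapping[str, Any], doc_id: str) -> MetadataRecord:
    """Flatten a nested JSON-like mapping into a :class:`MetadataRecord`.

    Leaf scalars are joined under dot-separated paths.  List elements merge
    under the parent path with values concatenated by single spaces, so an
    array of objects contributes one merged field per sub-path and the
    pairing between sibling values inside each object is lost.

    An empty tree yields a valid record with empty fields and catch-all.
    """
    if not doc_id:
        raise ValueError("doc_id must be non-empty")
    collected: dict[str, list[str]] = {}
    _walk(raw, "", collected)
    fields = {path: " ".join(v for v in values if v != "") or ""
              for path, values in collected.items()}
    # drop fields that rendered to nothing at all (e.g. only nulls)
    fields = {p: t for p, t in fields.items() if t != ""}
    if not fields:
        logger.info("record %s flattened to an empty document", doc_id)
    catchall = " ".join(fields[p] for p in sorted(fields))
    return MetadataRecord(doc_id=doc_id, fields=fields, catchall=catchall)


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# Unicode word-boundary style segmentation: runs of letters/digits/marks,
# kept together across a single medial apostrophe (can't), full stop or comma
# (3.14, example.com).  Hyphens, slashes and other punctuation break tokens,
# so "IL-6" segments as ["il", "6"].  Pure-punctuation segments never match.
_WORD_RE = re.compile(r"[^\W_]+(?:['’.,][^\W_]+)*", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Segment ``text`` into case-folded word tokens.

    Segmentation follows Unicode word boundaries (letters, digits and marks
    form tokens; medial apostrophe/period/comma do not split).  Order and
    duplicates are preserved; the empty string yields an empty list.
    """
    if not text:
        return []
    # casefold, not lower: case-insensitive matching for one-way case pairs
    folded = unicodedata.normalize("NFC", text).casefold()
    return [m.group(0) for m in _WORD_RE.finditer(folded)]


# ---------------------------------------------------------------------------
# Corpus loading
# ---------------------------------------------------------------------------

def _iter_json_units(path: Path) -> Iterator[tuple[str, str]]:
    """Yield ``(unit_id, raw_text)`` for each input unit under ``path``.

    A directory yields one unit per ``*.json`` file (unit id = filename stem);
    a ``.jsonl``/``.ndjson`` file yields one unit per non-blank line
    (unit id = ``stem-<lineno>``).
    """
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.is_file() and p.suffix.lower() == ".json")
        for p in files:
            yield p.stem, p.read_text(encoding="utf-8")
    else:
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    yield f"{path.stem}-{lineno}", line


def load_corpus(path: str | Path, id_field: str | None = None) -> Corpus:
    """Load a corpus from a directory of JSON files or a JSON-lines file.

    Unparseable units are skipped (counted in ``n_skipped`` and logged with
    the parse error) rather than aborting the import.  Numbers keep their
    source lexical form.  ``id_field`` names a top-level field to use as the
    document id instead of the filename stem / line number.

    Raises :class:`CorpusError` if the path is missing, no unit parses, or
    two records share a doc id.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus path does not exist: {path}")
    records: list[MetadataRecord] = []
    seen: set[str] = set()
    n_skipped = 0
    for unit_id, text in _iter_json_units(path):
        try:
            raw = json.loads(text, parse_int=str, parse_float=str)
            if not isinstance(raw, Mapping):
                raise ValueError("top-level JSON value is not an object")
            doc_id = unit_id
            if id_field is not None:
                value = raw.get(id_field)
                if value is None or str(value) == "":
                    raise ValueError(f"missing id field {id_field!r}")
                doc_id = str(value)
            rec = flatten_record(raw, doc_id)
        except (ValueError, json.JSONDecodeError) as exc:
            n_skipped += 1
            logger.warning("skipping unit %s: %s", unit_id, exc)
            continue
        if rec.doc_id in seen:
            raise CorpusError(f"duplicate doc_id {rec.doc_id!r} in {path}")
        seen.add(rec.doc_id)
        records.append(rec)
    if not records:
        raise CorpusError(f"no parseable records under {path}")
    return Corpus(records=records, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Inverted index
# ---------------------------------------------------------------------------

@dataclass
class InvertedIndex:
    """Term postings plus the collection statistics BM25 needs.

    ``postings[t]`` lists ``(doc_id, term_frequency)`` sorted by doc id;
    ``doc_len`` is the catch-all token count per document.
    """

    postings: dict[str, list[tuple[str, int]]]
    doc_len: dict[str, int]

    @property
    def n_docs(self) -> int:
        return len(self.doc_len)

    @property
    def avg_len(self) -> float:
        if not self.doc_len:
            return 0.0
        return sum(self.doc_len.values()) / len(self.doc_len)

    def df(self, term: str) -> int:
        return len(self.postings.get(term, ()))

    def tf(self, term: str, doc_id: str) -> int:
        for d, f in self.postings.get(term, ()):
            if d == doc_id:
                return f
        return 0

    # -- persistence: a single portable JSON archive ------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "meshir-index-v1",
            "doc_len": self.doc_len,
            "postings": {t: [[d, f] for d, f in pl]
                         for t, pl in self.postings.items()},
        }
        Path(path).write_text(json.dumps(payload, ensure_ascii=False),
                              encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "InvertedIndex":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "meshir-index-v1":
            raise CorpusError(f"not a meshir index archive: {path}")
        postings = {t: [(d, int(f)) for d, f in pl]
                    for t, pl in payload["postings"].items()}
        return cls(postings=postings,
                   doc_len={d: int(n) for d, n in payload["doc_len"].items()})


def build_index(corpus: Corpus) -> InvertedIndex:
    """Build the inverted index over the catch-all text of every record."""
    if not corpus.records:
        raise CorpusError("cannot index an empty corpus")
    counts: dict[str, dict[str, int]] = {}
    doc_len: dict[str, int] = {}
    for rec in corpus.records:
        tokens = tokenize(rec.catchall)
        doc_len[rec.doc_id] = len(tokens)
        for tok in tokens:
            per_term = counts.setdefault(tok, {})
            per_term[rec.doc_id] = per_term.get(rec.doc_id, 0) + 1
    postings = {t: sorted(per.items()) for t, per in counts.items()}
    return InvertedIndex(postings=postings, doc_len=doc_len)
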