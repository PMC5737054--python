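"""Ordered MeSH-synonym lookup from a local table, with a per-token cap.

Query expansion bridges vocabulary mismatch by adding controlled-vocabulary
synonyms (Medical Subject Headings) for each query token.  Lookups here go
through a local TSV table rather than a live Entrez/E-utilities call, which
makes runs reproducible: the table's file order is the canonical term order,
and the first ``max_terms`` entries per token are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "SynonymTable",
    "ExpansionConfig",
    "load_synonyms",
    "lookup",
    "build_expansion_bag",
    "parse_ratio",
]


@dataclass
class SynonymTable:
    """Maps a lowercase query token to an ordered list of MeSH term strings."""

    entries: dict[str, list[str]]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ExpansionConfig:
    """Expansion knobs: per-token synonym cap and clause weight ratio.

    ``max_terms`` is the cap K on synonyms fetched per query token (K = 0
    disables expansion).  The ratio ``mesh_weight:baseline_weight`` sets how
    much the expansion clause contributes relative to the baseline clause;
    "1:5" means the MeSH clause counts one-fifth as much.
    """

    max_terms: int = 5
    mesh_weight: float = 1.0
    baseline_weight: float = 5.0

    def __post_init__(self) -> None:
        if self.max_terms < 0:
            raise ValueError("max_terms must be >= 0")
        if self.baseline_weight <= 0:
            raise ValueError("baseline_weight must be positive")
        if self.max_terms > 0 and self.mesh_weight <= 0:
            raise ValueError("mesh_weight must be positive when expansion is on")

    @property
    def ratio(self) -> str:
        def fmt(x: float) -> str:
            return str(int(x)) if float(x).is_integer() else str(x)
        return f"{fmt(self.mesh_weight)}:{fmt(self.baseline_weight)}"


def parse_ratio(text: str) -> tuple[float, float]:
    """Parse ``"a:b"`` as ``(mesh_weight, baseline_weight)``."""
    parts = text.split(":")
    if len(parts) != 2:
        raise ValueError(f"ratio must look like 'a:b', got {text!r}")
    try:
        mesh, base = float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise ValueError(f"non-numeric ratio {text!r}") from exc
    if mesh <= 0 or base <= 0:
        raise ValueError(f"ratio components must be positive: {text!r}")
    return mesh, base


def load_synonyms(path: str | Path) -> SynonymTable:
    """Load a ``token<TAB>term<TAB>term...`` synonym table.

    Term order is preserved exactly as in the file.  A token appearing on
    several lines merges by appending previously unseen terms.  Lines without
    a tab (and hence without any term) are skipped with a warning; ``#``
    comment lines and blank lines are ignored.  An empty file yields an
    empty (valid) table.
    """
    path = Path(path)
    entries: dict[str, list[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            token, terms = parts[0].lower(), [t for t in parts[1:] if t]
            if not token or not terms:
                logger.warning("%s:%d: malformed synonym line skipped", path, lineno)
                continue
            bucket = entries.setdefault(token, [])
            for term in terms:
                if term not in bucket:
                    bucket.append(term)
    return SynonymTable(entries=entries)


def lookup(table: SynonymTable, token: str, max_terms: int) -> list[str]:
    """First ``min(max_terms, available)`` synonyms for ``token`` in table order.

    Unknown tokens (and ``max_terms = 0``) return an empty list.
    """
    if max_terms < 0:
        raise ValueError("max_terms must be >= 0")
    if max_terms == 0:
        return []
    return list(table.entries.get(token.lower(), ())[:max_terms])


def build_expansion_bag(baseline_tokens: Sequence[str], table: SynonymTable,
                        max_terms: int) -> list[str]:
    """Build the expansion token bag for a preprocessed baseline query.

    For each baseline token in order, up to ``max_terms`` MeSH terms are
    fetched; all term strings are concatenated into a single string which is
    then tokenized with the index tokenizer (multiword headings decompose
    into word tokens).  Tokens already in the bag are dropped, preserving
    first-occurrence order, so repeated synonym words cannot silently
    inflate the clause weight.
    """
    pieces: list[str] = []
    for token in baseline_tokens:
        pieces.extend(lookup(table, token, max_terms))
    bag: list[str] = []
    seen: set[str] = set()
    for tok in tokenize(" ".join(pieces)):
        if tok not in seen:
            seen.add(tok)
            bag.append(tok)
    return bag
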