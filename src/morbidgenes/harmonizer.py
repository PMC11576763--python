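"""Gene symbol harmonization against an HGNC-style symbol table.

Evidence for one gene arrives from six databases under whatever symbol each
snapshot happens to carry — the current approved symbol, a previous symbol,
or an alias. Before scoring, every symbol is resolved to a single stable
HGNC accession so that points from different sources land on the same gene
record.

Resolution is tiered: an exact match to an approved symbol always wins;
otherwise previous symbols are consulted, then aliases. A query whose best
match collides between two or more distinct genes is deliberately dropped
(``unmapped`` with ``ambiguous=True``) rather than attributed arbitrarily —
silently crediting evidence to the wrong gene is worse than losing a record,
and unmapped queries are logged so curators can inspect them.

Matching is case-sensitive after whitespace trimming: HGNC symbols are
case-significant and source snapshots emit canonical case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("hgnc_id", "symbol", "status", "prev_symbols", "alias_symbols")


class MatchTier(str, Enum):
    APPROVED = "approved"
    PREVIOUS = "previous"
    ALIAS = "alias"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class SymbolEntry:
    """One gene in the symbol table."""

    hgnc_id: str
    approved_symbol: str
    previous_symbols: frozenset[str]
    alias_symbols: frozenset[str]
    status: str  # "approved" | "withdrawn"


@dataclass
class SymbolTable:
    """HGNC-style symbol table with tiered lookup indices.

    Withdrawn entries are retained (so record counts are honest) but never
    participate in matching.
    """

    entries: list[SymbolEntry]
    _approved: dict[str, SymbolEntry] = field(init=False, repr=False)
    _previous: dict[str, set[str]] = field(init=False, repr=False)
    _alias: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        for e in self.entries:
            if e.hgnc_id in seen_ids:
                raise IntegrityError(f"duplicate hgnc_id {e.hgnc_id!r} in symbol table")
            seen_ids.add(e.hgnc_id)
            if e.approved_symbol in e.alias_symbols:
                raise IntegrityError(
                    f"{e.hgnc_id}: approved symbol {e.approved_symbol!r} listed as its own alias"
                )
        self._approved = {}
        self._previous = {}
        self._alias = {}
        for e in self.entries:
            if e.status != "approved":
                continue
            if e.approved_symbol in self._approved:
                raise IntegrityError(
                    f"approved symbol {e.approved_symbol!r} shared by two approved entries"
                )
            self._approved[e.approved_symbol] = e
            for s in e.previous_symbols:
                self._previous.setdefault(s, set()).add(e.hgnc_id)
            for s in e.alias_symbols:
                self._alias.setdefault(s, set()).add(e.hgnc_id)
        self._by_id = {e.hgnc_id: e for e in self.entries}

    def entry(self, hgnc_id: str) -> SymbolEntry:
        return self._by_id[hgnc_id]


@dataclass(frozen=True)
class Resolution:
    """Outcome of resolving one query symbol.

    ``match_tier == UNMAPPED`` iff ``hgnc_id is None``; ``ambiguous`` is only
    ever true for unmapped results (the query hit >= 2 genes at its best tier).
    """

    query: str
    hgnc_id: str | None
    current_symbol: str | None
    match_tier: MatchTier
    ambiguous: bool = False


def _split_multi(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(s for s in str(cell).split("|") if s)


def load_symbol_table(path: str | Path) -> SymbolTable:
    """Load an HGNC-style TSV (pipe-separated multi-valued cells)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"symbol table {path}: missing required column {col!r}")
    entries = [
        SymbolEntry(
            hgnc_id=row.hgnc_id,
            approved_symbol=row.symbol,
            previous_symbols=_split_multi(row.prev_symbols),
            alias_symbols=_split_multi(row.alias_symbols),
            status=row.status,
        )
        for row in df.itertuples(index=False)
    ]
    return SymbolTable(entries)


def resolve_symbol(query: str, table: SymbolTable) -> Resolution:
    """Resolve one symbol with approved > previous > alias precedence.

    Never raises for non-empty input; the worst outcome is an unmapped
    resolution. Raises ``ValueError`` for an empty (or all-whitespace) query.
    """
    q = query.strip()
    if not q:
        raise ValueError("empty query symbol")
    hit = table._approved.get(q)
    if hit is not None:
        return Resolution(q, hit.hgnc_id, hit.approved_symbol, MatchTier.APPROVED)
    for tier, index in ((MatchTier.PREVIOUS, table._previous), (MatchTier.ALIAS, table._alias)):
        ids = index.get(q)
        if not ids:
            continue
        if len(ids) > 1:
            logger.info("symbol %r ambiguous at tier %s (%d genes); unmapped", q, tier.value, len(ids))
            return Resolution(q, None, None, MatchTier.UNMAPPED, ambiguous=True)
        (hgnc_id,) = ids
        entry = table.entry(hgnc_id)
        return Resolution(q, hgnc_id, entry.approved_symbol, tier)
    logger.info("symbol %r unmapped", q)
    return Resolution(q, None, None, MatchTier.UNMAPPED)
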