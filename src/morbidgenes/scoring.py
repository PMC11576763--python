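"""Morbidscore computation, panel inclusion and minimum-score filtering.

The Morbidscore of a gene is the number of source databases (out of six)
whose inclusion criterion the gene satisfies — one point per database, never
more, regardless of how many qualifying records a database holds. A gene
enters the panel when at least one criterion is met (score >= 1); genes kept
at score 1 are deliberately retained as limited-evidence candidates, and
users filter them out downstream by raising the minimum score.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .adapters import Source, SourceEvidence
from .errors import IntegrityError

ALL_SOURCES: tuple[Source, ...] = tuple(Source)


@dataclass(frozen=True)
class GeneEvidence:
    """A harmonized gene with exactly one evidence slot per source.

    A source from which no record mapped to the gene still has a slot
    (``met=False, count=0``), so the score is always a count over six slots.
    """

    hgnc_id: str
    symbol: str
    evidence: Mapping[Source, SourceEvidence]

    def __post_init__(self) -> None:
        missing = [s.value for s in ALL_SOURCES if s not in self.evidence]
        if missing or len(self.evidence) != len(ALL_SOURCES):
            raise IntegrityError(
                f"{self.hgnc_id}: evidence must cover all six sources exactly once"
                + (f" (missing {missing})" if missing else "")
            )


@dataclass(frozen=True)
class PanelRow:
    """One included gene: score, per-source met flags and detail strings."""

    hgnc_id: str
    symbol: str
    morbidscore: int
    flags: Mapping[Source, bool]
    details: Mapping[Source, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        score = sum(1 for s in ALL_SOURCES if self.flags.get(s, False))
        if score != self.morbidscore:
            raise IntegrityError(
                f"{self.hgnc_id}: morbidscore {self.morbidscore} != {score} true flags"
            )

    @property
    def met_sources(self) -> frozenset[Source]:
        return frozenset(s for s in ALL_SOURCES if self.flags.get(s, False))


def compute_morbidscore(gene: GeneEvidence) -> int:
    """Count of sources whose criterion is met; each awards a single point."""
    return sum(1 for s in ALL_SOURCES if gene.evidence[s].met)


def include_gene(score: int) -> bool:
    """Panel inclusion rule: at least one criterion fulfilled."""
    if not 0 <= score <= 6:
        raise ValueError(f"morbidscore out of range: {score}")
    return score >= 1


def row_from_evidence(gene: GeneEvidence) -> PanelRow:
    """Materialize a panel row; the score is recomputed from flags, never stored."""
    flags = {s: gene.evidence[s].met for s in ALL_SOURCES}
    details = {s: gene.evidence[s].detail for s in ALL_SOURCES}
    return PanelRow(gene.hgnc_id, gene.symbol, sum(flags.values()), flags, details)


def filter_by_min_score(rows: Sequence[PanelRow], min_score: int) -> list[PanelRow]:
    """Rows with morbidscore >= min_score, original order preserved.

    ``min_score`` ranges 0..7; 7 is an exclusive sentinel that always yields
    an empty panel.
    """
    if not 0 <= min_score <= 7:
        raise ValueError(f"min_score out of range 0..7: {min_score}")
    return [r for r in rows if r.morbidscore >= min_score]
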