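"""Panel summary statistics: score distribution, exclusive source
intersections (UpSet semantics), PanelApp instance overlap and version trend.

Intersections are *exclusive*: each gene is assigned to exactly the
combination equal to its set of met sources, so combination counts sum to the
panel size and, per source, the combinations containing it sum to that
source's total. These are the invariants an UpSet plot visualizes; here they
are emitted as plain TSV tables and checked rather than drawn.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

from .adapters import PanelAppGeneEntry, PanelAppInstance, Source
from .panel_io import PanelVersion, validate_label
from .scoring import ALL_SOURCES

SCORE_RANGE = range(1, 7)


@dataclass(frozen=True)
class ScoreHistogram:
    """Gene counts per Morbidscore value 1..6; counts sum to the panel size."""

    counts: dict[int, int]
    total: int

    def tail_sum(self, min_score: int) -> int:
        return sum(c for s, c in self.counts.items() if s >= min_score)


@dataclass(frozen=True)
class IntersectionTable:
    """Exclusive source-combination counts plus per-source totals.

    ``rows`` are (combination, count) sorted by count descending, ties by the
    combination's sorted source names; ``singles[source]`` is the number of
    panel genes with that source's flag true (the grey bars of an UpSet plot).
    """

    rows: tuple[tuple[frozenset[Source], int], ...]
    singles: dict[Source, int]


def score_distribution(panel: PanelVersion) -> ScoreHistogram:
    counts = {s: 0 for s in SCORE_RANGE}
    for row in panel.rows:
        counts[row.morbidscore] += 1
    return ScoreHistogram(counts=counts, total=len(panel))


def _combo_key(combo: frozenset[Source]) -> tuple[str, ...]:
    return tuple(sorted(s.value for s in combo))


def exclusive_intersections(panel: PanelVersion) -> IntersectionTable:
    groups: dict[frozenset[Source], int] = {}
    singles = {s: 0 for s in ALL_SOURCES}
    for row in panel.rows:
        combo = row.met_sources
        groups[combo] = groups.get(combo, 0) + 1
        for s in combo:
            singles[s] += 1
    rows = tuple(
        sorted(groups.items(), key=lambda item: (-item[1], _combo_key(item[0])))
    )
    return IntersectionTable(rows=rows, singles=singles)


def exclusive_to_instance(
    entries: Iterable[PanelAppGeneEntry],
    resolver: Callable[[str], str | None] | None = None,
    min_level: int = 3,
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Partition green genes by PanelApp instance membership.

    Returns ``(shared, ge_only, aus_only)`` gene-identifier sets over entries
    with confidence level >= ``min_level``. ``resolver`` maps a raw symbol to
    a stable identifier (returning ``None`` to drop unmappable symbols); by
    default the raw symbol itself is the identifier. The three sets are
    pairwise disjoint and partition the green-gene union.
    """
    green: dict[PanelAppInstance, set[str]] = {i: set() for i in PanelAppInstance}
    for e in entries:
        if e.confidence_level < min_level:
            continue
        ident = resolver(e.gene_symbol) if resolver is not None else e.gene_symbol
        if ident is not None:
            green[e.instance].add(ident)
    ge = green[PanelAppInstance.GENOMICS_ENGLAND]
    aus = green[PanelAppInstance.AUSTRALIA]
    return frozenset(ge & aus), frozenset(ge - aus), frozenset(aus - ge)


def version_trend(panels: Sequence[PanelVersion]) -> list[tuple[str, int]]:
    """(label, size) per panel, sorted chronologically by (year, month)."""
    labels = [p.label for p in panels]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate panel labels in version trend")
    return [
        (p.label, len(p))
        for p in sorted(panels, key=lambda p: validate_label(p.label))
    ]


def write_stats(
    out_dir: str | Path,
    histogram: ScoreHistogram,
    intersections: IntersectionTable,
    trend: Sequence[tuple[str, int]] | None = None,
) -> list[Path]:
    """Write score_distribution.tsv, intersections.tsv and (optionally)
    version_trend.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out / "score_distribution.tsv"
    lines = ["morbidscore\tn_genes"]
    lines += [f"{s}\t{histogram.counts[s]}" for s in SCORE_RANGE]
    lines.append(f"total\t{histogram.total}")
    p.write_text("\n".join(lines) + "\n", newline="\n")
    written.append(p)

    p = out / "intersections.tsv"
    lines = ["sources\tn_genes"]
    lines += [
        "{}\t{}".format("+".join(_combo_key(combo)), count)
        for combo, count in intersections.rows
    ]
    lines.append("")
    lines.append("source\ttotal_genes")
    lines += [f"{s.value}\t{intersections.singles[s]}" for s in ALL_SOURCES]
    p.write_text("\n".join(lines) + "\n", newline="\n")
    written.append(p)

    if trend is not None:
        p = out / "version_trend.tsv"
        lines = ["label\tn_genes"]
        lines += [f"{label}\t{size}" for label, size in trend]
        p.write_text("\n".join(lines) + "\n", newline="\n")
        written.append(p)
    return written
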