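"""Versioned panel assembly, serialization and version diffing.

A panel build is labeled ``v<YYYY>_<MM>`` (the panel is refreshed monthly from
new source snapshots) and is fully reproducible: identical evidence yields a
byte-identical TSV. Each version is written as two files —

* ``<label>.tsv`` — one row per included gene: accession, symbol,
  Morbidscore, six TRUE/FALSE source flags, six detail columns. Rows are
  sorted by symbol (ties by accession), flags use TRUE/FALSE, lines end with
  ``\\n`` and fields may not contain tabs or newlines, so two builds of the
  same data diff cleanly line-by-line.
* ``<label>.meta.json`` — build date, per-source snapshot provenance (file
  name, record count, checksum) and the effective configuration.

``diff_panels`` compares two versions into added / removed / score-changed
gene sets, the monthly changelog a panel consumer reviews before updating.
"""

from __future__ import annotations

import json
import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from datetime import date
from pathlib import Path

from .adapters import Source
from .errors import FormatError, IntegrityError
from .scoring import ALL_SOURCES, GeneEvidence, PanelRow, compute_morbidscore, include_gene, row_from_evidence

LABEL_RE = re.compile(r"^v(\d{4})_(\d{2})$")

_FLAG_COLUMNS = [s.value for s in ALL_SOURCES]
_DETAIL_COLUMNS = [f"{s.value}_detail" for s in ALL_SOURCES]
PANEL_COLUMNS = ["hgnc_id", "symbol", "morbidscore", *_FLAG_COLUMNS, *_DETAIL_COLUMNS]


def validate_label(label: str) -> tuple[int, int]:
    """Return (year, month) or raise for a label not matching v<YYYY>_<MM>."""
    m = LABEL_RE.match(label)
    if not m:
        raise IntegrityError(f"panel label {label!r} does not match v<YYYY>_<MM>")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise IntegrityError(f"panel label {label!r} has month outside 01..12")
    return year, month


def _row_sort_key(row: PanelRow) -> tuple[str, str]:
    return (row.symbol, row.hgnc_id)


@dataclass(frozen=True)
class PanelVersion:
    """A labeled, dated panel build with per-source provenance."""

    label: str
    build_date: date
    source_meta: Mapping[str, Mapping[str, object]]
    rows: tuple[PanelRow, ...]

    def __post_init__(self) -> None:
        validate_label(self.label)
        seen: set[str] = set()
        for row in self.rows:
            if row.hgnc_id in seen:
                raise IntegrityError(f"duplicate hgnc_id {row.hgnc_id!r} in panel {self.label}")
            seen.add(row.hgnc_id)
            if row.morbidscore < 1:
                raise IntegrityError(
                    f"{row.hgnc_id}: panel rows must have morbidscore >= 1"
                )
        keys = [_row_sort_key(r) for r in self.rows]
        if keys != sorted(keys):
            raise IntegrityError(f"panel {self.label}: rows not sorted by (symbol, hgnc_id)")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(r.hgnc_id for r in self.rows)

    def row_by_id(self, hgnc_id: str) -> PanelRow:
        for r in self.rows:
            if r.hgnc_id == hgnc_id:
                return r
        raise KeyError(hgnc_id)


@dataclass(frozen=True)
class PanelDiff:
    """Gene-level changes between two panel versions."""

    from_label: str
    to_label: str
    added: frozenset[str]
    removed: frozenset[str]
    score_changed: frozenset[tuple[str, int, int]]


def build_panel(
    evidence: Sequence[GeneEvidence],
    label: str,
    source_meta: Mapping[str, Mapping[str, object]] | None = None,
    build_date: date | None = None,
) -> PanelVersion:
    """Assemble a panel: one row per gene meeting at least one criterion.

    Deterministic for identical inputs; duplicate accessions in the evidence
    are an integrity error (harmonization must have collapsed them already).
    """
    validate_label(label)
    seen: set[str] = set()
    for g in evidence:
        if g.hgnc_id in seen:
            raise IntegrityError(f"duplicate hgnc_id {g.hgnc_id!r} in evidence")
        seen.add(g.hgnc_id)
    rows = [
        row_from_evidence(g) for g in evidence if include_gene(compute_morbidscore(g))
    ]
    rows.sort(key=_row_sort_key)
    return PanelVersion(
        label=label,
        build_date=build_date or date.today(),
        source_meta=dict(source_meta or {}),
        rows=tuple(rows),
    )


def _check_field(value: str) -> str:
    if "\t" in value or "\n" in value or "\r" in value:
        raise FormatError(f"field contains tab/newline: {value!r}")
    return value


def write_panel(
    panel: PanelVersion,
    out_dir: str | Path,
    extra_meta: Mapping[str, object] | None = None,
) -> tuple[Path, Path]:
    """Write ``<label>.tsv`` and ``<label>.meta.json``; returns both paths.

    ``extra_meta`` entries (e.g. the effective build config) are merged into
    the sidecar; they are provenance only and are not read back.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv_path = out / f"{panel.label}.tsv"
    meta_path = out / f"{panel.label}.meta.json"

    lines = ["\t".join(PANEL_COLUMNS)]
    for row in panel.rows:
        fields = [
            _check_field(row.hgnc_id),
            _check_field(row.symbol),
            str(row.morbidscore),
            *("TRUE" if row.flags.get(s, False) else "FALSE" for s in ALL_SOURCES),
            *(_check_field(row.details.get(s, "")) for s in ALL_SOURCES),
        ]
        lines.append("\t".join(fields))
    tsv_path.write_text("\n".join(lines) + "\n", newline="\n")

    meta = {
        "label": panel.label,
        "build_date": panel.build_date.isoformat(),
        "n_genes": len(panel),
        "source_meta": {k: dict(v) for k, v in sorted(panel.source_meta.items())},
    }
    if extra_meta:
        meta.update(extra_meta)
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return tsv_path, meta_path


def read_panel(path: str | Path) -> PanelVersion:
    """Read a panel TSV (+ sidecar); ``read(write(p)) == p`` on all fields."""
    tsv_path = Path(path)
    meta_path = tsv_path.parent / (tsv_path.name[: -len(".tsv")] + ".meta.json")
    if not tsv_path.exists():
        raise FileNotFoundError(tsv_path)
    text = tsv_path.read_text()
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise FormatError(f"panel file {tsv_path}: empty")
    header = lines[0].split("\t")
    if header != PANEL_COLUMNS:
        raise FormatError(
            f"panel file {tsv_path}: header {header!r} does not match {PANEL_COLUMNS!r}"
        )
    rows: list[PanelRow] = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(PANEL_COLUMNS):
            raise FormatError(f"panel file {tsv_path}: line {i} has {len(fields)} fields")
        rec = dict(zip(PANEL_COLUMNS, fields))
        flags: dict[Source, bool] = {}
        for s in ALL_SOURCES:
            raw = rec[s.value]
            if raw not in ("TRUE", "FALSE"):
                raise FormatError(
                    f"panel file {tsv_path}: line {i} flag {s.value}={raw!r} not TRUE/FALSE"
                )
            flags[s] = raw == "TRUE"
        details = {s: rec[f"{s.value}_detail"] for s in ALL_SOURCES}
        try:
            row = PanelRow(rec["hgnc_id"], rec["symbol"], int(rec["morbidscore"]), flags, details)
        except ValueError as exc:
            raise FormatError(f"panel file {tsv_path}: line {i}: {exc}") from exc
        rows.append(row)

    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        label = meta["label"]
        build_date = date.fromisoformat(meta["build_date"])
        source_meta = meta.get("source_meta", {})
    else:
        label = tsv_path.name[: -len(".tsv")]
        build_date = date(1970, 1, 1)
        source_meta = {}
    return PanelVersion(label=label, build_date=build_date, source_meta=source_meta, rows=tuple(rows))


def diff_panels(a: PanelVersion, b: PanelVersion) -> PanelDiff:
    """Changes from version ``a`` to version ``b``.

    ``added`` are genes only in ``b``, ``removed`` only in ``a``;
    ``score_changed`` holds (accession, old, new) for genes in both whose
    score moved. diff(a, b).added == diff(b, a).removed by construction.
    """
    ids_a, ids_b = a.gene_ids, b.gene_ids
    shared = ids_a & ids_b
    score_a = {r.hgnc_id: r.morbidscore for r in a.rows}
    score_b = {r.hgnc_id: r.morbidscore for r in b.rows}
    changed = frozenset(
        (g, score_a[g], score_b[g]) for g in shared if score_a[g] != score_b[g]
    )
    return PanelDiff(
        from_label=a.label,
        to_label=b.label,
        added=frozenset(ids_b - ids_a),
        removed=frozenset(ids_a - ids_b),
        score_changed=changed,
    )


def write_diff(diff: PanelDiff, path: str | Path) -> Path:
    """Write a diff report TSV: change, hgnc_id, old_score, new_score."""
    out = Path(path)
    lines = ["change\thgnc_id\told_score\tnew_score"]
    for g in sorted(diff.added):
        lines.append(f"added\t{g}\t\t")
    for g in sorted(diff.removed):
        lines.append(f"removed\t{g}\t\t")
    for g, old, new in sorted(diff.score_changed):
        lines.append(f"score_changed\t{g}\t{old}\t{new}")
    out.write_text("\n".join(lines) + "\n", newline="\n")
    return out
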