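"""End-to-end panel build: parse snapshots, harmonize, score, assemble.

This is the monthly-update pipeline in library form. Every record from every
source is resolved against the symbol table; records whose symbol cannot be
mapped to a single current gene are excluded from scoring and tallied per
source in the build log, so curators can audit what was dropped. Criterion
thresholds are configurable but default to the published rule set.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

from . import adapters
from .adapters import PanelAppInstance, Source
from .harmonizer import SymbolTable, load_symbol_table, resolve_symbol
from .panel_io import PanelVersion, build_panel, validate_label
from .scoring import ALL_SOURCES, GeneEvidence

logger = logging.getLogger(__name__)


@dataclass
class BuildConfig:
    """Input paths, version label and criterion thresholds for one build."""

    hgnc: Path
    omim: Path
    clinvar: Path
    hgmd: Path
    panelapp_ge: Path
    panelapp_aus: Path
    gencc: Path
    sysndd: Path
    label: str
    out_dir: Path = Path(".")
    clinvar_min: int = 4
    hgmd_min: int = 4
    hgmd_classes: tuple[str, ...] = ("DM",)
    panelapp_min_level: int = 3
    omim_mapping_keys: tuple[int, ...] = (3, 4)
    build_date: date | None = None

    _PATH_KEYS = ("hgnc", "omim", "clinvar", "hgmd", "panelapp_ge", "panelapp_aus", "gencc", "sysndd", "out_dir")

    def validate(self) -> None:
        try:
            validate_label(self.label)
        except Exception as exc:  # a bad label in config is a usage error
            raise ValueError(str(exc)) from exc
        for name in ("clinvar_min", "hgmd_min", "panelapp_min_level"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for p in self._PATH_KEYS[:-1]:
            if not Path(getattr(self, p)).exists():
                raise FileNotFoundError(f"input path for {p} not found: {getattr(self, p)}")

    @classmethod
    def from_dict(cls, data: dict) -> "BuildConfig":
        kwargs = dict(data)
        for key in cls._PATH_KEYS:
            if key in kwargs:
                kwargs[key] = Path(kwargs[key])
        if "hgmd_classes" in kwargs:
            kwargs["hgmd_classes"] = tuple(kwargs["hgmd_classes"])
        if "omim_mapping_keys" in kwargs:
            kwargs["omim_mapping_keys"] = tuple(int(k) for k in kwargs["omim_mapping_keys"])
        if isinstance(kwargs.get("build_date"), str):
            kwargs["build_date"] = date.fromisoformat(kwargs["build_date"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            **{k: str(getattr(self, k)) for k in self._PATH_KEYS},
            "label": self.label,
            "clinvar_min": self.clinvar_min,
            "hgmd_min": self.hgmd_min,
            "hgmd_classes": list(self.hgmd_classes),
            "panelapp_min_level": self.panelapp_min_level,
            "omim_mapping_keys": list(self.omim_mapping_keys),
            "build_date": self.build_date.isoformat() if self.build_date else None,
        }

    @classmethod
    def for_universe(cls, universe_dir: str | Path, label: str, **overrides) -> "BuildConfig":
        """Config pointing at a fixture-universe directory layout."""
        d = Path(universe_dir)
        return cls(
            hgnc=d / "hgnc.tsv",
            omim=d / "omim.tsv",
            clinvar=d / "clinvar.tsv",
            hgmd=d / "hgmd.tsv",
            panelapp_ge=d / "panelapp_ge",
            panelapp_aus=d / "panelapp_aus",
            gencc=d / "gencc.tsv",
            sysndd=d / "sysndd.tsv",
            label=label,
            **overrides,
        )


@dataclass
class BuildLog:
    """Per-source parse and harmonization tallies for one build."""

    record_counts: dict[str, int] = field(default_factory=dict)
    unmapped: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "record_counts": dict(sorted(self.record_counts.items())),
            "unmapped": {k: sorted(v) for k, v in sorted(self.unmapped.items())},
        }


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for f in sorted(path.glob("*.json")):
            h.update(f.name.encode())
            h.update(f.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def _parse_all(config: BuildConfig) -> dict[Source, list]:
    return {
        Source.OMIM: adapters.parse_omim(config.omim),
        Source.CLINVAR: adapters.parse_clinvar(config.clinvar),
        Source.HGMD: adapters.parse_hgmd(config.hgmd),
        Source.PANELAPP: (
            adapters.parse_panelapp(config.panelapp_ge, PanelAppInstance.GENOMICS_ENGLAND)
            + adapters.parse_panelapp(config.panelapp_aus, PanelAppInstance.AUSTRALIA)
        ),
        Source.SYSNDD: adapters.parse_sysndd(config.sysndd),
        Source.GENCC: adapters.parse_gencc(config.gencc),
    }


def harmonize_records(
    records_by_source: dict[Source, list], table: SymbolTable, log: BuildLog | None = None
) -> dict[str, dict[Source, list]]:
    """Group records by resolved gene accession; drop and tally unmapped."""
    cache: dict[str, tuple[str | None, str | None]] = {}
    grouped: dict[str, dict[Source, list]] = {}
    for source, records in records_by_source.items():
        unmapped: list[str] = []
        for rec in records:
            raw = adapters.record_symbol(rec)
            if raw not in cache:
                res = resolve_symbol(raw, table)
                cache[raw] = (res.hgnc_id, res.current_symbol)
            hgnc_id, _ = cache[raw]
            if hgnc_id is None:
                unmapped.append(raw)
                continue
            grouped.setdefault(hgnc_id, {s: [] for s in ALL_SOURCES})[source].append(rec)
        if log is not None:
            log.record_counts[source.value] = len(records)
            log.unmapped[source.value] = sorted(set(unmapped))
        if unmapped:
            logger.info("%s: %d records with unmapped symbols excluded", source.value, len(set(unmapped)))
    return grouped


def run_build(config: BuildConfig) -> tuple[PanelVersion, BuildLog]:
    """Execute a full build and return the panel plus its build log."""
    config.validate()
    table = load_symbol_table(config.hgnc)
    records_by_source = _parse_all(config)
    log = BuildLog()
    grouped = harmonize_records(records_by_source, table, log)

    evidence: list[GeneEvidence] = []
    for hgnc_id in sorted(grouped):
        slots = {
            source: adapters.criterion_for(
                source,
                grouped[hgnc_id][source],
                clinvar_min=config.clinvar_min,
                hgmd_min=config.hgmd_min,
                hgmd_classes=frozenset(config.hgmd_classes),
                panelapp_min_level=config.panelapp_min_level,
                omim_mapping_keys=frozenset(config.omim_mapping_keys),
            )
            for source in ALL_SOURCES
        }
        evidence.append(GeneEvidence(hgnc_id, table.entry(hgnc_id).approved_symbol, slots))

    source_meta = {
        source.value: {
            "file": Path(path).name,
            "records": log.record_counts[source.value],
            "sha256": _checksum(Path(path)),
        }
        for source, path in (
            (Source.OMIM, config.omim),
            (Source.CLINVAR, config.clinvar),
            (Source.HGMD, config.hgmd),
            (Source.SYSNDD, config.sysndd),
            (Source.GENCC, config.gencc),
        )
    }
    source_meta[Source.PANELAPP.value] = {
        "file": f"{Path(config.panelapp_ge).name}+{Path(config.panelapp_aus).name}",
        "records": log.record_counts[Source.PANELAPP.value],
        "sha256": hashlib.sha256(
            (_checksum(Path(config.panelapp_ge)) + _checksum(Path(config.panelapp_aus))).encode()
        ).hexdigest(),
    }
    panel = build_panel(evidence, config.label, source_meta, build_date=config.build_date)
    return panel, log
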