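"""Source snapshot parsers and the six per-source inclusion criteria.

Each of the six databases contributes at most one point to a gene's
Morbidscore. A source's criterion reduces all of that source's records for
one gene to a single :class:`SourceEvidence` verdict:

1. **OMIM** — at least one phenotype association with molecular basis known
   (mapping key 3 or 4 by default), excluding provisional (``?`` prefix),
   susceptibility (``{...}``) and nondisease (``[...]``) entries.
2. **ClinVar** — at least four (likely) pathogenic variants, counting somatic
   origins but excluding copy-number variants and conflicting classifications.
3. **HGMD** — at least four pathogenic variants (class ``DM`` by default;
   ``DM?`` can be admitted via configuration).
4. **PanelApp** — a green curation status (confidence level >= 3) on at least
   one panel in either the Genomics England or the Australia instance.
5. **SysNDD** — an entity with status "definitive"/"definite".
6. **GenCC** — at least one submission classified "Definitive".

Every criterion is a pure function of its gene's records: record order never
changes the verdict, and an empty record list yields ``met=False, count=0``.
Thresholds are keyword-configurable but default to the published values.
"""

from __future__ import annotations

import json
import logging
import re
from collections.abc import Sequence
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)


class Source(str, Enum):
    """The six evidence databases, in panel column order."""

    OMIM = "omim"
    CLINVAR = "clinvar"
    HGMD = "hgmd"
    PANELAPP = "panelapp"
    SYSNDD = "sysndd"
    GENCC = "gencc"


class PanelAppInstance(str, Enum):
    GENOMICS_ENGLAND = "GenomicsEngland"
    AUSTRALIA = "Australia"


@dataclass(frozen=True)
class SourceEvidence:
    """One source's verdict for one gene.

    ``count`` is the number of qualifying items behind the verdict; for the
    variant-count sources (ClinVar, HGMD) ``met`` is exactly ``count >= 4``
    under default thresholds, so ``met`` always implies ``count >= 1``.
    """

    source: Source
    met: bool
    count: int
    detail: str = ""

    def __post_init__(self) -> None:
        if self.met and self.count < 1:
            raise ValueError(f"{self.source.value}: met evidence requires count >= 1")
        if self.count < 0:
            raise ValueError("count must be non-negative")


# --------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class OmimAssociation:
    gene_symbol: str
    mim_number: int
    phenotype_label: str  # raw, prefix markers retained
    mapping_key: int | None


@dataclass(frozen=True)
class ClinvarVariantRecord:
    variation_id: int
    gene_symbol: str
    variant_type: str
    clinical_significance: str
    origin: str
    assembly: str


HGMD_CLASSES = frozenset({"DM", "DM?", "DP", "DFP", "FP", "R"})


@dataclass(frozen=True)
class HgmdVariantRecord:
    gene_symbol: str
    variant_class: str
    variant_id: str


@dataclass(frozen=True)
class PanelAppGeneEntry:
    instance: PanelAppInstance
    panel_id: int
    panel_name: str
    gene_symbol: str
    confidence_level: int


@dataclass(frozen=True)
class GenccSubmission:
    gene_symbol: str
    hgnc_id: str | None
    disease_label: str
    classification: str
    submitter: str


@dataclass(frozen=True)
class SysnddEntry:
    gene_symbol: str
    status: str
    disease_label: str


def _read_tsv(path: str | Path, required: Sequence[str], label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{label} file {path}: missing required column {col!r}")
    return df


# --------------------------------------------------------------------------
# OMIM

# "<label>, <phenoMIM> (<mappingKey>)" — greedy label so embedded commas stay
# in the label; the six-digit MIM and single-digit key anchor the tail.
_OMIM_ENTRY_RE = re.compile(r"^(?P<label>.+),\s*(?P<mim>\d{6})\s*\((?P<key>\d)\)$")
_OMIM_KEY_ONLY_RE = re.compile(r"^(?P<label>.+?)\s*\((?P<key>\d)\)$")


def parse_omim(path: str | Path) -> list[OmimAssociation]:
    """Parse a genemap2-style TSV into one association per phenotype entry.

    Phenotype cells hold semicolon-separated entries; prefix markers are kept
    verbatim in the label. Entries whose mapping-key parenthetical cannot be
    parsed are retained with ``mapping_key=None`` and a logged warning.
    """
    df = _read_tsv(path, ("Gene Symbols", "MIM Number", "Phenotypes"), "OMIM")
    out: list[OmimAssociation] = []
    cols = df[["Gene Symbols", "MIM Number", "Phenotypes"]]
    for symbols_cell, mim_cell, pheno_cell in cols.itertuples(index=False, name=None):
        symbol = str(symbols_cell).split(",")[0].strip()
        mim = int(mim_cell)
        cell = str(pheno_cell).strip()
        if not cell:
            continue
        for entry in cell.split(";"):
            entry = entry.strip()
            if not entry:
                continue
            m = _OMIM_ENTRY_RE.match(entry)
            if m:
                out.append(OmimAssociation(symbol, mim, m["label"].strip(), int(m["key"])))
                continue
            m = _OMIM_KEY_ONLY_RE.match(entry)
            if m:
                out.append(OmimAssociation(symbol, mim, m["label"].strip(), int(m["key"])))
            else:
                logger.warning("OMIM entry without parsable mapping key: %r", entry)
                out.append(OmimAssociation(symbol, mim, entry, None))
    return out


def omim_association_qualifies(
    assoc: OmimAssociation, mapping_keys: frozenset[int] = frozenset({3, 4})
) -> bool:
    label = assoc.phenotype_label.strip()
    if label.startswith("?"):
        return False  # provisional association
    if label.startswith("{") and label.endswith("}"):
        return False  # susceptibility phenotype
    if label.startswith("[") and label.endswith("]"):
        return False  # nondisease trait
    return assoc.mapping_key in mapping_keys


def omim_criterion(
    associations: Sequence[OmimAssociation],
    *,
    mapping_keys: frozenset[int] = frozenset({3, 4}),
) -> SourceEvidence:
    qualifying = [a for a in associations if omim_association_qualifies(a, mapping_keys)]
    detail = qualifying[0].phenotype_label if qualifying else ""
    return SourceEvidence(Source.OMIM, bool(qualifying), len(qualifying), detail)


# --------------------------------------------------------------------------
# ClinVar

_CLINVAR_COLUMNS = (
    "VariationID",
    "Type",
    "GeneSymbol",
    "ClinicalSignificance",
    "OriginSimple",
    "Assembly",
)

_CNV_TYPES = frozenset({"copy number gain", "copy number loss"})


def parse_clinvar(path: str | Path) -> list[ClinvarVariantRecord]:
    """Parse a variant_summary-style TSV.

    Rows are deduplicated by (VariationID, GeneSymbol) keeping the first
    occurrence, so per-assembly duplicates count once; semicolon-separated
    multi-gene cells expand to one record per symbol.
    """
    df = _read_tsv(path, _CLINVAR_COLUMNS, "ClinVar")
    out: list[ClinvarVariantRecord] = []
    seen: set[tuple[int, str]] = set()
    for row in df.itertuples(index=False):
        vid_raw = row.VariationID
        try:
            vid = int(vid_raw)
        except ValueError:
            logger.warning("ClinVar row skipped: non-integer VariationID %r", vid_raw)
            continue
        for symbol in str(row.GeneSymbol).split(";"):
            symbol = symbol.strip()
            if not symbol or (vid, symbol) in seen:
                continue
            seen.add((vid, symbol))
            out.append(
                ClinvarVariantRecord(
                    variation_id=vid,
                    gene_symbol=symbol,
                    variant_type=row.Type,
                    clinical_significance=row.ClinicalSignificance,
                    origin=row.OriginSimple,
                    assembly=row.Assembly,
                )
            )
    return out


def clinvar_record_qualifies(rec: ClinvarVariantRecord) -> bool:
    sig = rec.clinical_significance.lower()
    if "pathogenic" not in sig or "conflicting" in sig:
        return False
    return rec.variant_type.lower() not in _CNV_TYPES


def clinvar_criterion(
    records: Sequence[ClinvarVariantRecord], *, min_count: int = 4
) -> SourceEvidence:
    count = sum(1 for r in records if clinvar_record_qualifies(r))
    detail = f"{count} (likely) pathogenic non-CNV variants" if count else ""
    return SourceEvidence(Source.CLINVAR, count >= min_count, count, detail)


# --------------------------------------------------------------------------
# HGMD


def parse_hgmd(path: str | Path) -> list[HgmdVariantRecord]:
    df = _read_tsv(path, ("gene", "variant_id", "variant_class"), "HGMD")
    out: list[HgmdVariantRecord] = []
    for row in df.itertuples(index=False):
        if row.variant_class not in HGMD_CLASSES:
            logger.warning("HGMD row skipped: unknown variant class %r", row.variant_class)
            continue
        out.append(HgmdVariantRecord(row.gene, row.variant_class, row.variant_id))
    return out


def hgmd_criterion(
    records: Sequence[HgmdVariantRecord],
    *,
    min_count: int = 4,
    pathogenic_classes: frozenset[str] = frozenset({"DM"}),
) -> SourceEvidence:
    count = sum(1 for r in records if r.variant_class in pathogenic_classes)
    detail = f"{count} {'/'.join(sorted(pathogenic_classes))} variants" if count else ""
    return SourceEvidence(Source.HGMD, count >= min_count, count, detail)


# --------------------------------------------------------------------------
# PanelApp


def parse_panelapp(dir_path: str | Path, instance: PanelAppInstance) -> list[PanelAppGeneEntry]:
    """Parse a directory of PanelApp-export-style JSON panel dumps."""
    out: list[PanelAppGeneEntry] = []
    for path in sorted(Path(dir_path).glob("*.json")):
        try:
            payload = json.loads(path.read_text())
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise FormatError(f"PanelApp file {path}: unparseable JSON ({exc})") from exc
        for gene in payload.get("genes", []):
            out.append(
                PanelAppGeneEntry(
                    instance=instance,
                    panel_id=int(payload["id"]),
                    panel_name=str(payload["name"]),
                    gene_symbol=str(gene["entity_name"]),
                    confidence_level=int(gene["confidence_level"]),
                )
            )
    return out


def panelapp_criterion(
    entries: Sequence[PanelAppGeneEntry], *, min_level: int = 3
) -> SourceEvidence:
    qualifying = [e for e in entries if e.confidence_level >= min_level]
    detail = "; ".join(f"{e.instance.value}:{e.panel_name}" for e in qualifying)
    return SourceEvidence(Source.PANELAPP, bool(qualifying), len(qualifying), detail)


# --------------------------------------------------------------------------
# GenCC


def parse_gencc(path: str | Path) -> list[GenccSubmission]:
    df = _read_tsv(path, ("gene_symbol", "hgnc_id", "disease", "classification", "submitter"), "GenCC")
    return [
        GenccSubmission(
            gene_symbol=row.gene_symbol,
            hgnc_id=row.hgnc_id or None,
            disease_label=row.disease,
            classification=row.classification,
            submitter=row.submitter,
        )
        for row in df.itertuples(index=False)
    ]


def gencc_criterion(submissions: Sequence[GenccSubmission]) -> SourceEvidence:
    qualifying = [s for s in submissions if s.classification.lower() == "definitive"]
    detail = qualifying[0].disease_label if qualifying else ""
    return SourceEvidence(Source.GENCC, bool(qualifying), len(qualifying), detail)


# --------------------------------------------------------------------------
# SysNDD

_SYSNDD_QUALIFYING = frozenset({"definitive", "definite"})


def parse_sysndd(path: str | Path) -> list[SysnddEntry]:
    df = _read_tsv(path, ("symbol", "status", "disease"), "SysNDD")
    return [
        SysnddEntry(row.symbol, row.status, row.disease) for row in df.itertuples(index=False)
    ]


def sysndd_criterion(entries: Sequence[SysnddEntry]) -> SourceEvidence:
    qualifying = [e for e in entries if e.status.lower() in _SYSNDD_QUALIFYING]
    detail = qualifying[0].disease_label if qualifying else ""
    return SourceEvidence(Source.SYSNDD, bool(qualifying), len(qualifying), detail)


def record_symbol(record: object) -> str:
    """The raw symbol carried by any source record type."""
    return record.gene_symbol  # type: ignore[attr-defined]


def criterion_for(
    source: Source,
    records: Sequence,
    *,
    clinvar_min: int = 4,
    hgmd_min: int = 4,
    hgmd_classes: frozenset[str] = frozenset({"DM"}),
    panelapp_min_level: int = 3,
    omim_mapping_keys: frozenset[int] = frozenset({3, 4}),
) -> SourceEvidence:
    """Dispatch to the right criterion with configured thresholds."""
    if source is Source.OMIM:
        return omim_criterion(records, mapping_keys=omim_mapping_keys)
    if source is Source.CLINVAR:
        return clinvar_criterion(records, min_count=clinvar_min)
    if source is Source.HGMD:
        return hgmd_criterion(records, min_count=hgmd_min, pathogenic_classes=hgmd_classes)
    if source is Source.PANELAPP:
        return panelapp_criterion(records, min_level=panelapp_min_level)
    if source is Source.SYSNDD:
        return sysndd_criterion(records)
    if source is Source.GENCC:
        return gencc_criterion(records)
    raise ValueError(f"unknown source {source!r}")
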