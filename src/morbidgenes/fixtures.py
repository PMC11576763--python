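"""Synthetic snapshot universes with planted ground truth.

Real builds consume point-in-time snapshots of six licensed or volatile
databases, so none of them can ship with the package. This module generates
a complete, self-consistent stand-in universe instead: an HGNC-style symbol
table plus all six source snapshots in exactly the dialects the adapters
consume, driven by a planted gene-by-source membership matrix that doubles
as the oracle for every downstream stage.

The generator plants, per gene and source:

* **members** — records that satisfy the source's criterion (e.g. 4–8
  pathogenic ClinVar variants, each emitted once per assembly to exercise
  deduplication; a green PanelApp entry; a "Definitive" GenCC submission);
* **non-members** — either nothing or records that fall short (0–3
  pathogenic variants);
* **decoys** — records matching every exclusion rule of the criteria
  (provisional/susceptibility/nondisease OMIM labels, low mapping keys,
  CNV and conflicting ClinVar rows, questioned HGMD classes, amber/red
  PanelApp entries, "Strong" GenCC, "Limited" SysNDD). Decoys never qualify,
  so raising their rates must never change the expected panel;
* **aliases** — a fraction of genes appear in one source under an alias
  symbol, so the end-to-end oracle only holds if harmonization recovers the
  planted identity.

Symbols are synthetic (GENE0001, alias AL0001, previous symbol PR0001) so no
real database content is reproduced. The same seed yields byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adapters import PanelAppInstance, Source
from .scoring import ALL_SOURCES, PanelRow

DECOY_CLASSES = (
    "omim_provisional",
    "omim_susceptibility",
    "omim_nondisease",
    "omim_low_mapping_key",
    "clinvar_cnv",
    "clinvar_conflicting",
    "hgmd_questionable",
    "panelapp_low_confidence",
    "gencc_strong",
    "sysndd_limited",
)

# Marginal membership probabilities loosely shaped like the real panel:
# OMIM/ClinVar/HGMD/PanelApp carry most genes, SysNDD is phenotype-specific
# and sparse, GenCC sits in between.
DEFAULT_MEMBERSHIP_PROBS: dict[Source, float] = {
    Source.OMIM: 0.60,
    Source.CLINVAR: 0.60,
    Source.HGMD: 0.60,
    Source.PANELAPP: 0.65,
    Source.SYSNDD: 0.15,
    Source.GENCC: 0.45,
}

_PANEL_NAMES = ("Mendeliome", "Neurodevelopmental disorders", "Cardiovascular disorders")
_PANEL_IDS = {PanelAppInstance.GENOMICS_ENGLAND: (100, 101, 102), PanelAppInstance.AUSTRALIA: (200, 201, 202)}


@dataclass
class FixtureSpec:
    """Parameters of one synthetic universe.

    ``membership`` may be an explicit n_genes x 6 boolean matrix (column
    order :data:`morbidgenes.scoring.ALL_SOURCES`); otherwise membership is
    drawn per source from ``membership_probs``. Count ranges are inclusive;
    member ranges must clear the criterion thresholds (>= 4) and non-member
    ranges must stay below them (<= 3) so the planted matrix is the exact
    oracle.
    """

    n_genes: int = 200
    membership: np.ndarray | None = None
    membership_probs: dict[Source, float] = field(
        default_factory=lambda: dict(DEFAULT_MEMBERSHIP_PROBS)
    )
    clinvar_count_range: tuple[int, int] = (4, 8)
    hgmd_count_range: tuple[int, int] = (4, 8)
    nonmember_count_range: tuple[int, int] = (0, 3)
    decoy_rates: dict[str, float] = field(
        default_factory=lambda: {name: 0.3 for name in DECOY_CLASSES}
    )
    alias_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_genes > 9000:
            raise ValueError("n_genes must be in 1..9000")
        if self.membership is not None:
            m = np.asarray(self.membership, dtype=bool)
            if m.shape != (self.n_genes, len(ALL_SOURCES)):
                raise ValueError(
                    f"membership matrix must be {self.n_genes} x {len(ALL_SOURCES)}"
                )
        for src, p in self.membership_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"membership probability for {src} outside [0, 1]")
        for name, p in self.decoy_rates.items():
            if name not in DECOY_CLASSES:
                raise ValueError(f"unknown decoy class {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"decoy rate for {name} outside [0, 1]")
        if not 0.0 <= self.alias_rate <= 1.0:
            raise ValueError("alias_rate outside [0, 1]")
        for lo, hi in (self.clinvar_count_range, self.hgmd_count_range):
            if not (4 <= lo <= hi):
                raise ValueError("member count ranges must satisfy 4 <= lo <= hi")
        lo, hi = self.nonmember_count_range
        if not (0 <= lo <= hi <= 3):
            raise ValueError("non-member count range must satisfy 0 <= lo <= hi <= 3")


@dataclass(frozen=True)
class GeneTruth:
    """Planted truth for one gene."""

    hgnc_id: str
    symbol: str
    memberships: frozenset[Source]
    counts: dict[Source, int]
    panelapp_instances: frozenset[PanelAppInstance]
    alias_symbol: str
    previous_symbol: str
    alias_source: Source | None  # source in which the alias is emitted

    @property
    def expected_score(self) -> int:
        return len(self.memberships)

    @property
    def expected_inclusion(self) -> bool:
        return self.expected_score >= 1


@dataclass(frozen=True)
class GroundTruth:
    """Planted matrix for a whole universe; the oracle for every stage."""

    genes: tuple[GeneTruth, ...]

    def by_id(self, hgnc_id: str) -> GeneTruth:
        for g in self.genes:
            if g.hgnc_id == hgnc_id:
                return g
        raise KeyError(hgnc_id)


def expected_panel(truth: GroundTruth) -> list[PanelRow]:
    """The panel the pipeline must produce: one row per gene with >= 1
    planted membership, flags equal to the planted matrix, sorted by
    (symbol, hgnc_id). Detail strings are not part of the oracle."""
    rows = [
        PanelRow(
            hgnc_id=g.hgnc_id,
            symbol=g.symbol,
            morbidscore=g.expected_score,
            flags={s: (s in g.memberships) for s in ALL_SOURCES},
        )
        for g in truth.genes
        if g.expected_inclusion
    ]
    rows.sort(key=lambda r: (r.symbol, r.hgnc_id))
    return rows


def _emitted_symbol(gene: GeneTruth, source: Source) -> str:
    return gene.alias_symbol if gene.alias_source is source else gene.symbol


def _write(path: Path, lines: list[str]) -> None:
    path.write_text("\n".join(lines) + "\n", newline="\n")


def generate_universe(spec: FixtureSpec, out_dir: str | Path) -> GroundTruth:
    """Generate all seven snapshot files plus a manifest under ``out_dir``.

    Returns the planted :class:`GroundTruth`. Identical (spec, seed) produce
    byte-identical files.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    n = spec.n_genes
    if spec.membership is not None:
        member = np.asarray(spec.membership, dtype=bool)
    else:
        probs = np.array([spec.membership_probs.get(s, 0.0) for s in ALL_SOURCES])
        member = rng.random((n, len(ALL_SOURCES))) < probs
    alias_flag = rng.random(n) < spec.alias_rate

    genes: list[GeneTruth] = []
    for i in range(n):
        symbol = f"GENE{i + 1:04d}"
        member_sources = frozenset(s for j, s in enumerate(ALL_SOURCES) if member[i, j])
        counts: dict[Source, int] = {}
        for src, (lo, hi) in (
            (Source.CLINVAR, spec.clinvar_count_range),
            (Source.HGMD, spec.hgmd_count_range),
        ):
            if src in member_sources:
                counts[src] = int(rng.integers(lo, hi + 1))
            else:
                nlo, nhi = spec.nonmember_count_range
                counts[src] = int(rng.integers(nlo, nhi + 1))
        counts[Source.OMIM] = int(rng.integers(1, 3)) if Source.OMIM in member_sources else 0
        counts[Source.GENCC] = int(rng.integers(1, 3)) if Source.GENCC in member_sources else 0
        counts[Source.SYSNDD] = 1 if Source.SYSNDD in member_sources else 0
        if Source.PANELAPP in member_sources:
            u = rng.random()
            if u < 0.5:
                instances = frozenset(PanelAppInstance)
            elif u < 0.75:
                instances = frozenset({PanelAppInstance.GENOMICS_ENGLAND})
            else:
                instances = frozenset({PanelAppInstance.AUSTRALIA})
        else:
            instances = frozenset()
        counts[Source.PANELAPP] = len(instances)
        alias_source: Source | None = None
        if alias_flag[i] and member_sources:
            ordered = sorted(member_sources, key=lambda s: s.value)
            alias_source = ordered[int(rng.integers(0, len(ordered)))]
        genes.append(
            GeneTruth(
                hgnc_id=f"HGNC:{10001 + i}",
                symbol=symbol,
                memberships=member_sources,
                counts=counts,
                panelapp_instances=instances,
                alias_symbol=f"AL{i + 1:04d}",
                previous_symbol=f"PR{i + 1:04d}",
                alias_source=alias_source,
            )
        )

    truth = GroundTruth(genes=tuple(genes))
    _write_hgnc(out / "hgnc.tsv", truth)
    _write_omim(out / "omim.tsv", truth, spec, rng)
    _write_clinvar(out / "clinvar.tsv", truth, spec, rng)
    _write_hgmd(out / "hgmd.tsv", truth, spec, rng)
    _write_panelapp(out, truth, spec, rng)
    _write_gencc(out / "gencc.tsv", truth, spec, rng)
    _write_sysndd(out / "sysndd.tsv", truth, spec, rng)

    manifest = {
        "n_genes": spec.n_genes,
        "explicit_membership": spec.membership is not None,
        "membership_probs": {s.value: p for s, p in sorted(spec.membership_probs.items())},
        "clinvar_count_range": list(spec.clinvar_count_range),
        "hgmd_count_range": list(spec.hgmd_count_range),
        "nonmember_count_range": list(spec.nonmember_count_range),
        "decoy_rates": dict(sorted(spec.decoy_rates.items())),
        "alias_rate": spec.alias_rate,
        "seed": spec.seed,
        "files": [
            "hgnc.tsv", "omim.tsv", "clinvar.tsv", "hgmd.tsv",
            "panelapp_ge/", "panelapp_aus/", "gencc.tsv", "sysndd.tsv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return truth


def _decoy(rng: np.random.Generator, spec: FixtureSpec, name: str) -> bool:
    return rng.random() < spec.decoy_rates.get(name, 0.0)


def _write_hgnc(path: Path, truth: GroundTruth) -> None:
    lines = ["hgnc_id\tsymbol\tstatus\tprev_symbols\talias_symbols"]
    for g in truth.genes:
        lines.append(
            f"{g.hgnc_id}\t{g.symbol}\tapproved\t{g.previous_symbol}\t{g.alias_symbol}"
        )
    # withdrawn entries must load but never match
    lines.append("HGNC:99998\tWDRN1\twithdrawn\t\t")
    lines.append("HGNC:99999\tWDRN2\twithdrawn\t\t")
    _write(path, lines)


def _write_omim(path: Path, truth: GroundTruth, spec: FixtureSpec, rng: np.random.Generator) -> None:
    lines = ["Gene Symbols\tMIM Number\tPhenotypes"]
    pheno_mim = 610000
    for i, g in enumerate(truth.genes):
        entries: list[str] = []
        for j in range(g.counts[Source.OMIM]):
            entries.append(f"Syndrome {g.symbol} type {j + 1}, {pheno_mim} (3)")
            pheno_mim += 1
        if _decoy(rng, spec, "omim_provisional"):
            entries.append(f"?Provisional disorder {g.symbol}, {pheno_mim} (3)")
            pheno_mim += 1
        if _decoy(rng, spec, "omim_susceptibility"):
            entries.append(f"{{Cancer, susceptibility to, {g.symbol}}}, {pheno_mim} (3)")
            pheno_mim += 1
        if _decoy(rng, spec, "omim_nondisease"):
            entries.append(f"[Blood group trait {g.symbol}], {pheno_mim} (3)")
            pheno_mim += 1
        if _decoy(rng, spec, "omim_low_mapping_key"):
            entries.append(f"Linkage phenotype {g.symbol}, {pheno_mim} (2)")
            pheno_mim += 1
        if entries:
            symbol = _emitted_symbol(g, Source.OMIM)
            lines.append(f"{symbol}\t{600001 + i}\t" + "; ".join(entries))
    _write(path, lines)


_CLINVAR_SIGS = ("Pathogenic", "Likely pathogenic", "Pathogenic/Likely pathogenic")
_CLINVAR_ORIGINS = ("germline", "somatic")


def _write_clinvar(path: Path, truth: GroundTruth, spec: FixtureSpec, rng: np.random.Generator) -> None:
    lines = ["VariationID\tType\tGeneSymbol\tClinicalSignificance\tOriginSimple\tAssembly"]
    vid = 100000

    def emit(symbol: str, vtype: str, sig: str, origin: str) -> None:
        nonlocal vid
        for assembly in ("GRCh37", "GRCh38"):  # same variant on both assemblies
            lines.append(f"{vid}\t{vtype}\t{symbol}\t{sig}\t{origin}\t{assembly}")
        vid += 1

    for g in truth.genes:
        symbol = _emitted_symbol(g, Source.CLINVAR)
        for k in range(g.counts[Source.CLINVAR]):
            emit(symbol, "single nucleotide variant", _CLINVAR_SIGS[k % 3], _CLINVAR_ORIGINS[k % 2])
        if _decoy(rng, spec, "clinvar_cnv"):
            emit(symbol, "copy number loss" if rng.random() < 0.5 else "copy number gain",
                 "Pathogenic", "germline")
        if _decoy(rng, spec, "clinvar_conflicting"):
            emit(symbol, "single nucleotide variant",
                 "Conflicting interpretations of pathogenicity", "germline")
    _write(path, lines)


def _write_hgmd(path: Path, truth: GroundTruth, spec: FixtureSpec, rng: np.random.Generator) -> None:
    lines = ["gene\tvariant_id\tvariant_class"]
    counter = 1
    for g in truth.genes:
        symbol = _emitted_symbol(g, Source.HGMD)
        for _ in range(g.counts[Source.HGMD]):
            lines.append(f"{symbol}\tCM{counter:06d}\tDM")
            counter += 1
        if _decoy(rng, spec, "hgmd_questionable"):
            lines.append(f"{symbol}\tCM{counter:06d}\tDM?")
            counter += 1
    _write(path, lines)


def _write_panelapp(out: Path, truth: GroundTruth, spec: FixtureSpec, rng: np.random.Generator) -> None:
    dirs = {
        PanelAppInstance.GENOMICS_ENGLAND: out / "panelapp_ge",
        PanelAppInstance.AUSTRALIA: out / "panelapp_aus",
    }
    panels: dict[PanelAppInstance, dict[int, list[dict[str, str]]]] = {
        inst: {pid: [] for pid in _PANEL_IDS[inst]} for inst in PanelAppInstance
    }
    for g in truth.genes:
        symbol = _emitted_symbol(g, Source.PANELAPP)
        for inst in sorted(g.panelapp_instances, key=lambda x: x.value):
            pid = _PANEL_IDS[inst][int(rng.integers(0, len(_PANEL_IDS[inst])))]
            level = 3 if rng.random() < 0.5 else 4
            panels[inst][pid].append(
                {"entity_name": symbol, "confidence_level": str(level)}
            )
        if _decoy(rng, spec, "panelapp_low_confidence"):
            inst = (
                PanelAppInstance.GENOMICS_ENGLAND
                if rng.random() < 0.5
                else PanelAppInstance.AUSTRALIA
            )
            pid = _PANEL_IDS[inst][int(rng.integers(0, len(_PANEL_IDS[inst])))]
            level = int(rng.integers(0, 3))  # red/amber, never green
            panels[inst][pid].append(
                {"entity_name": symbol, "confidence_level": str(level)}
            )
    for inst, directory in dirs.items():
        directory.mkdir(parents=True, exist_ok=True)
        for pid, name in zip(_PANEL_IDS[inst], _PANEL_NAMES):
            payload = {
                "id": pid,
                "name": f"{name} ({inst.value})",
                "genes": sorted(panels[inst][pid], key=lambda d: d["entity_name"]),
            }
            (directory / f"panel_{pid}.json").write_text(
                json.dumps(payload, indent=1, sort_keys=True) + "\n"
            )


def _write_gencc(path: Path, truth: GroundTruth, spec: FixtureSpec, rng: np.random.Generator) -> None:
    lines = ["gene_symbol\thgnc_id\tdisease\tclassification\tsubmitter"]
    submitters = ("Fixture Lab A", "Fixture Lab B")
    for g in truth.genes:
        symbol = _emitted_symbol(g, Source.GENCC)
        hgnc = "" if g.alias_source is Source.GENCC else g.hgnc_id
        for k in range(g.counts[Source.GENCC]):
            lines.append(
                f"{symbol}\t{hgnc}\t{g.symbol}-related disorder\tDefinitive\t{submitters[k % 2]}"
            )
        if _decoy(rng, spec, "gencc_strong"):
            cls = "Strong" if rng.random() < 0.5 else "Moderate"
            lines.append(f"{symbol}\t{hgnc}\t{g.symbol}-related disorder\t{cls}\tFixture Lab C")
    _write(path, lines)


def _write_sysndd(path: Path, truth: GroundTruth, spec: FixtureSpec, rng: np.random.Generator) -> None:
    lines = ["symbol\tstatus\tdisease"]
    for g in truth.genes:
        symbol = _emitted_symbol(g, Source.SYSNDD)
        if g.counts[Source.SYSNDD]:
            lines.append(f"{symbol}\tDefinitive\t{g.symbol}-related NDD")
        if _decoy(rng, spec, "sysndd_limited"):
            lines.append(f"{symbol}\tLimited\t{g.symbol}-related NDD (limited)")
    _write(path, lines)
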