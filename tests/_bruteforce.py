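"""Independent brute-force oracle over fixture snapshot files.

Re-derives every source's per-gene (met, count) verdict straight from the
files with pandas/json row filtering — no code shared with the adapters or
the scoring pipeline — so adapter results can be checked against a second,
dumber route.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from morbidgenes.adapters import Source

_ENTRY_RE = re.compile(r"^(?P<label>.+),\s*\d{6}\s*\((?P<key>\d)\)$")


def symbol_map(universe_dir: Path) -> dict[str, str]:
    """Raw symbol -> hgnc_id, approved symbols first, then unique prev/alias."""
    df = pd.read_csv(universe_dir / "hgnc.tsv", sep="\t", dtype=str, keep_default_na=False)
    df = df[df["status"] == "approved"]
    mapping: dict[str, str] = {row["symbol"]: row["hgnc_id"] for _, row in df.iterrows()}
    for col in ("prev_symbols", "alias_symbols"):
        tally: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            for sym in filter(None, row[col].split("|")):
                tally.setdefault(sym, set()).add(row["hgnc_id"])
        for sym, ids in tally.items():
            if sym not in mapping and len(ids) == 1:
                mapping[sym] = next(iter(ids))
    return mapping


def _qualifying_omim(label: str, key: str | None) -> bool:
    label = label.strip()
    if label.startswith(("?", "{", "[")):
        return False
    return key in ("3", "4")


def omim_counts(universe_dir: Path, symbols: dict[str, str]) -> dict[str, int]:
    df = pd.read_csv(universe_dir / "omim.tsv", sep="\t", dtype=str, keep_default_na=False)
    counts: dict[str, int] = {}
    for _, row in df.iterrows():
        gene = symbols.get(row["Gene Symbols"].split(",")[0].strip())
        if gene is None:
            continue
        for entry in filter(None, (e.strip() for e in row["Phenotypes"].split(";"))):
            m = _ENTRY_RE.match(entry)
            if m and _qualifying_omim(m["label"], m["key"]):
                counts[gene] = counts.get(gene, 0) + 1
    return counts


def clinvar_counts(universe_dir: Path, symbols: dict[str, str]) -> dict[str, int]:
    df = pd.read_csv(universe_dir / "clinvar.tsv", sep="\t", dtype=str, keep_default_na=False)
    df = df.assign(GeneSymbol=df["GeneSymbol"].str.split(";")).explode("GeneSymbol")
    df["GeneSymbol"] = df["GeneSymbol"].str.strip()
    df = df.drop_duplicates(subset=["VariationID", "GeneSymbol"])
    sig = df["ClinicalSignificance"].str.lower()
    keep = sig.str.contains("pathogenic") & ~sig.str.contains("conflicting")
    keep &= ~df["Type"].str.lower().isin(["copy number gain", "copy number loss"])
    df = df[keep]
    counts: dict[str, int] = {}
    for sym, n in df["GeneSymbol"].value_counts().items():
        gene = symbols.get(sym)
        if gene is not None:
            counts[gene] = counts.get(gene, 0) + int(n)
    return counts


def hgmd_counts(universe_dir: Path, symbols: dict[str, str], classes=("DM",)) -> dict[str, int]:
    df = pd.read_csv(universe_dir / "hgmd.tsv", sep="\t", dtype=str, keep_default_na=False)
    df = df[df["variant_class"].isin(classes)]
    counts: dict[str, int] = {}
    for sym, n in df["gene"].value_counts().items():
        gene = symbols.get(sym)
        if gene is not None:
            counts[gene] = counts.get(gene, 0) + int(n)
    return counts


def panelapp_counts(universe_dir: Path, symbols: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for sub in ("panelapp_ge", "panelapp_aus"):
        for path in sorted((universe_dir / sub).glob("*.json")):
            payload = json.loads(path.read_text())
            for g in payload["genes"]:
                if int(g["confidence_level"]) >= 3:
                    gene = symbols.get(g["entity_name"])
                    if gene is not None:
                        counts[gene] = counts.get(gene, 0) + 1
    return counts


def gencc_counts(universe_dir: Path, symbols: dict[str, str]) -> dict[str, int]:
    df = pd.read_csv(universe_dir / "gencc.tsv", sep="\t", dtype=str, keep_default_na=False)
    df = df[df["classification"].str.lower() == "definitive"]
    counts: dict[str, int] = {}
    for sym, n in df["gene_symbol"].value_counts().items():
        gene = symbols.get(sym)
        if gene is not None:
            counts[gene] = counts.get(gene, 0) + int(n)
    return counts


def sysndd_counts(universe_dir: Path, symbols: dict[str, str]) -> dict[str, int]:
    df = pd.read_csv(universe_dir / "sysndd.tsv", sep="\t", dtype=str, keep_default_na=False)
    df = df[df["status"].str.lower().isin(["definitive", "definite"])]
    counts: dict[str, int] = {}
    for sym, n in df["symbol"].value_counts().items():
        gene = symbols.get(sym)
        if gene is not None:
            counts[gene] = counts.get(gene, 0) + int(n)
    return counts


MET_THRESHOLDS = {
    Source.OMIM: 1,
    Source.CLINVAR: 4,
    Source.HGMD: 4,
    Source.PANELAPP: 1,
    Source.SYSNDD: 1,
    Source.GENCC: 1,
}


def all_verdicts(universe_dir: Path) -> dict[Source, dict[str, tuple[bool, int]]]:
    """Per source: hgnc_id -> (met, count), computed by brute force."""
    universe_dir = Path(universe_dir)
    symbols = symbol_map(universe_dir)
    raw = {
        Source.OMIM: omim_counts(universe_dir, symbols),
        Source.CLINVAR: clinvar_counts(universe_dir, symbols),
        Source.HGMD: hgmd_counts(universe_dir, symbols),
        Source.PANELAPP: panelapp_counts(universe_dir, symbols),
        Source.SYSNDD: sysndd_counts(universe_dir, symbols),
        Source.GENCC: gencc_counts(universe_dir, symbols),
    }
    return {
        src: {g: (n >= MET_THRESHOLDS[src], n) for g, n in counts.items()}
        for src, counts in raw.items()
    }
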