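# morbidgenes

An evidence-aggregating gene panel builder for rare-disease diagnostics.

Diagnostic labs overlay exome data with a virtual panel of genes that have at
least minimal published evidence of disease causality. Maintaining such a
broad panel by hand is impractical for small labs: new gene–disease
associations appear continuously and are scattered across databases that
disagree in scope and curation depth. This package builds that panel
automatically from local snapshots of six sources — OMIM, ClinVar, HGMD,
PanelApp (Genomics England and Australia instances), SysNDD and GenCC — and
keeps it versioned, diffable and filterable.

## The Morbidscore

Every gene symbol found in any snapshot is first harmonized against an
HGNC-style symbol table (approved > previous > alias precedence; ambiguous
symbols are dropped and logged). Each source then awards the gene one point
if its inclusion criterion holds:

| source   | criterion                                                                 |
|----------|---------------------------------------------------------------------------|
| OMIM     | ≥ 1 phenotype with molecular basis known (mapping key 3/4), excluding provisional `?`, susceptibility `{…}` and nondisease `[…]` entries |
| ClinVar  | ≥ 4 (likely) pathogenic variants, somatic included, CNVs and conflicting records excluded |
| HGMD     | ≥ 4 pathogenic (`DM`) variants                                            |
| PanelApp | green status (confidence ≥ 3) on ≥ 1 panel in either instance             |
| SysNDD   | an entity with status "definitive"                                         |
| GenCC    | ≥ 1 submission classified "Definitive"                                     |

The Morbidscore is the number of criteria met (0–6); a gene enters the panel
when the score is ≥ 1. Low-score genes are retained deliberately — a
single-source gene may still explain a case — and users filter at their own
threshold (`morbidgenes filter PANEL 4`).

## Worked example

Real database snapshots are licensed and point-in-time, so the package ships
a generator for synthetic snapshot universes with planted ground truth:

```bash
morbidgenes simulate --n-genes 50 --seed 3 --out-dir u1
# universe with 50 genes (50 panel-eligible) -> u1

morbidgenes build --universe u1 --label v2024_10 --out-dir out
# v2024_10: 50 genes -> out/v2024_10.tsv

morbidgenes stats out/v2024_10.tsv --out-dir out/stats
cat out/stats/score_distribution.tsv
# morbidscore  n_genes
# 1            5
# 2            12
# 3            19
# 4            12
# 5            2
# 6            0
# total        50

morbidgenes filter out/v2024_10.tsv 4 --out out/filtered
# 14 genes with morbidscore >= 4 -> out/filtered/v2024_10.tsv

morbidgenes diff out/v2024_10.tsv out/v2024_10.tsv
# v2024_10 -> v2024_10: +0 -0 ~0
```

The 50-gene panel here contains every simulated gene because each had at
least one planted source; 14 of them (the histogram tail for scores 4–6:
12 + 2 + 0) survive the stricter filter. `build` also
writes `v2024_10.meta.json` (label, build date, per-source checksums,
effective thresholds) and `v2024_10.build_log.json` (record counts and any
unmapped symbols per source).

The same operations are available as a library:

```python
from morbidgenes import FixtureSpec, generate_universe, BuildConfig, run_build

truth = generate_universe(FixtureSpec(n_genes=200, seed=1), "universe/")
panel, log = run_build(BuildConfig.for_universe("universe/", "v2024_10"))
```

## Layout

- `morbidgenes.harmonizer` — HGNC-style symbol resolution
- `morbidgenes.adapters` — the six snapshot parsers and criteria
- `morbidgenes.scoring` — Morbidscore, inclusion rule, filtering
- `morbidgenes.panel_io` — versioned panel TSV/JSON, diffs
- `morbidgenes.statistics` — histogram, UpSet-style intersections, trend
- `morbidgenes.fixtures` — synthetic universes with planted truth
- `morbidgenes.build` / `morbidgenes.cli` — pipeline and command line

See `docs/methods.md` for the method, parameter defaults and limitations.
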