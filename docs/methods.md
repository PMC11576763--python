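# Methods

## The model

The package treats "is this gene diagnostically relevant?" as a vote among
six independent evidence databases. Each database casts at most one vote (a
point toward the Morbidscore), decided by a per-source inclusion criterion
applied to that database's records for the gene. The panel is the set of
genes with at least one vote. The score is deliberately unweighted: the goal
is a broad first-line panel with a transparent, reproducible inclusion
logic and minimal manual curation, not a curated gold standard. Consumers
who want higher specificity raise the minimum score at filter time instead
of the builder deciding for them.

The assumption behind the single-point rule is that databases are
correlated but not redundant: most well-established genes are supported by
four or more sources, while genuinely new or niche associations may appear
in only one. Keeping score-1 genes trades precision for sensitivity, which
is the right trade for a screening panel that feeds case-specific variant
review.

## Criteria and their thresholds

All thresholds are configuration-exposed; the defaults are the method's
published rule set.

- **OMIM** (`omim_mapping_keys`, default `{3, 4}`): an association counts
  only if its phenotype has a known molecular basis (mapping key 3) or is a
  chromosomal syndrome (key 4). Keys 1–2 are linkage/phenotype-only and not
  attributable to the gene, so they are excluded by default. Labels carrying
  the genemap2 prefix conventions are excluded: `?` (provisional), `{…}`
  (susceptibility), `[…]` (nondisease trait). The brackets case goes beyond
  the bare "provisional and susceptibility" exclusions because nondisease
  traits are not diagnostic findings either.
- **ClinVar** (`clinvar_min`, default 4): a variant counts if its clinical
  significance contains "pathogenic" but not "conflicting"
  (case-insensitive), capturing `Pathogenic`, `Likely pathogenic` and the
  combined `Pathogenic/Likely pathogenic` while rejecting conflicting and
  benign records. Copy-number types are excluded; origin (germline/somatic)
  is ignored. Variants are deduplicated by (VariationID, gene) so
  per-assembly duplicate rows count once — naive row counting would double
  every variant. Review status (star rating) is ignored.
- **HGMD** (`hgmd_min` 4, `hgmd_classes` `{DM}`): only confirmed
  disease-causing mutations count by default; `DM?` (questioned) can be
  admitted via configuration but is off because its pathogenicity is
  explicitly doubted.
- **PanelApp** (`panelapp_min_level` 3): confidence ≥ 3 is the "green"
  tier; one green entry on any panel of either instance suffices. Multiple
  green panels still yield one point.
- **SysNDD / GenCC**: the qualifying status is the controlled-vocabulary
  term "Definitive" (SysNDD also accepts the spelling "definite");
  "Strong" and below do not qualify. Mapping the looser word "definite" to
  GenCC's `Definitive` (and not `Strong`) is this package's reading of the
  closest controlled term.

## Symbol harmonization

Aggregating by raw symbol string would scatter one gene's evidence across
its synonyms. Every record's symbol is resolved against an HGNC-style table
with tier precedence approved > previous > alias, case-sensitive after
whitespace trimming (HGNC symbols are case-significant). A symbol matching
previous/alias symbols of two or more genes at its best tier is *unmapped*
rather than guessed: silently crediting the wrong gene is worse than
dropping a record, and unmapped symbols are tallied per source in the build
log. Panel rows therefore always carry a stable HGNC accession, and scores
are recomputed from the six met flags at build time rather than stored.

## Panel files, versioning, diffs

A build is labeled `v<YYYY>_<MM>` and is deterministic: rows sorted by
(symbol, accession), TRUE/FALSE flags, `\n` line endings, tabs forbidden
inside fields, so identical inputs give byte-identical TSVs and two
versions diff cleanly. Provenance (file names, record counts, SHA-256
checksums, effective thresholds) lives in a JSON sidecar, keeping the TSV a
plain downloadable grid. `diff_panels` reports added/removed genes and
score changes; by construction `|b| = |a| − |removed| + |added|`.

Statistics are exclusive-intersection (UpSet) semantics: each gene belongs
to exactly the combination equal to its met-source set, so combination
counts sum to the panel size and per-source totals are recoverable from the
table. Output is TSV; plotting is left to downstream notebooks.

## The synthetic universe generator

Real snapshots are licensed (HGMD, OMIM) or point-in-time (all), so testing
uses generated universes with planted ground truth. For each gene the
generator draws a six-source membership vector (defaults: OMIM/ClinVar/HGMD
0.60, PanelApp 0.65, GenCC 0.45, SysNDD 0.15 — shaped like the real panel,
where the four big sources dominate and the phenotype-specific SysNDD is
sparse) or accepts an explicit matrix. Members receive records that satisfy
the criterion (4–8 qualifying variants for ClinVar/HGMD, each ClinVar
variant emitted on both assemblies to exercise deduplication; green
PanelApp entries placed in both instances with probability 0.5, otherwise
in one); non-members receive 0–3 qualifying variants or nothing. Every
exclusion rule has a decoy class (provisional/susceptibility/nondisease
OMIM labels, mapping-key-2 entries, CNV and conflicting ClinVar rows, `DM?`,
amber/red PanelApp entries, `Strong` GenCC, `Limited` SysNDD), emitted at
configurable rates, and a configurable fraction of genes appear in one
source under an alias so the oracle only holds if harmonization works.
Membership and count draws precede decoy draws, so changing decoy rates
never changes the expected panel.

What the generator does **not** emulate: realistic marginal distributions
of the real databases (correlated memberships, panel sizes, label text),
multi-gene ClinVar rows beyond the dialect's semicolon convention, monthly
drift beyond explicitly edited membership matrices, or real HGNC content
(symbols are synthetic `GENE0001`-style; aliases `AL0001`, previous symbols
`PR0001`). Passing tests therefore demonstrate correctness of parsing,
harmonization, criteria logic, scoring, serialization and statistics — not
calibration against any real database's content.

## Numerical and procedural choices

- Determinism everywhere: a single `numpy` generator seeded from the spec;
  fixed iteration and sort orders; fixed file formatting. Same seed, same
  bytes.
- Ties in intersection tables break by lexicographic source names; panel
  rows tie-break by accession.
- Degenerate inputs: empty snapshot files yield empty record lists, genes
  absent from a source get `met=False, count=0` slots, an empty panel is
  valid and serializable.
- The minimum-score filter accepts 0..7; 7 is an exclusive sentinel making
  "empty panel" expressible.
- Problem sizes: unit universes of 120 genes, the end-to-end suite uses 20
  randomized universes of 50–500 genes, and the acceptance script a
  300-gene universe with a 12-gain/3-loss simulated next month — large
  enough that every criterion, decoy class and tier is exercised many times,
  small enough to run in seconds.

## Limitations

- Gene-level resolution only: no inheritance modes, allelic disorders or
  phenotype links; sources are snapshots, not live APIs.
- The "definite"→`Definitive` GenCC mapping and the `DM`-only HGMD default
  are judgment calls left configurable.
- Absolute sizes of real panels cannot be reproduced without the licensed
  snapshots; correctness claims rest on the planted-truth equivalence.
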