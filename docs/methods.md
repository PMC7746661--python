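# Methods

## The data model

A *record* is one source observation that a caterpillar of a given moth
species feeds and develops on a given plant: fields are the moth binomial,
the verbatim plant-name string, the source database tag, a
wild/captive-or-introduced setting flag, and an optional `questionable`
flag set at source (defaulting to false; questionable records are removed
with a logged count, never re-derived). The dataset is treated as strictly
qualitative — record frequency carries no information, because it mostly
reflects collecting effort and local plant availability — so the pipeline
only ever asks whether an association is documented, not how often.

The identity of a record, used for deduplication, is the quadruple
(moth species, plant identity at the finest resolved rank, source,
setting). Including the source keeps independently reported associations
distinguishable; including the setting keeps a wild and a captive
observation of the same association both visible, because the summary
tables report wild and captive columns separately. Plant identity is the
resolved species binomial when available, otherwise the resolved genus; a
genus-only record never collapses onto a species-level record of the same
genus, since they carry different amounts of information. Unresolved plant
names fall back to their normalized verbatim string so distinct unknown
names are not merged. First occurrence wins; deduplication is idempotent
and order-stable.

## Name reconciliation

`normalize_name` reduces a verbatim string to `Genus` or `Genus epithet`:
whitespace collapse, hybrid-marker removal, genus capitalisation, epithet
lower-casing, truncation at infraspecific rank markers (`var.`, `subsp.`,
…) and removal of author citations and open-nomenclature qualifiers
(`sp.`, `cf.`, `aff.`); qualifier presence is reported so genus-only
identifications can be treated as such downstream. Author detection is
heuristic — any capitalised or parenthesised token after the genus, except
an all-caps word of three or more letters, which is read as a shouted
epithet. The function is idempotent.

Resolution is entirely local-table driven for reproducibility without
network access: a plant lookup (genus → family → order, family →
angiosperm/gymnosperm, plus a synonym map applied to the normalized name
before rank lookup, at full-name or genus level) and a moth checklist
(genus → family/subfamily/tribe plus the described species count used as
the sampling-coverage denominator). Fuzzy matching is deliberately out of
scope. Unresolved plants are excluded from all counts but reported in the
audit trail, never silently dropped; moths whose genus is absent from the
checklist are retained with empty higher ranks and flagged.

## Summary tables

DS1 has one row per moth species with at least one record and 21 columns:
moth taxonomy, then distinct counts and alphabetically sorted `"; "`-joined
name lists of plant genera, species, families and orders — wild columns
first, then the `_Capt` variants. Genus-only plant records contribute to
the genus/family/order lists but not the species list. DS2 has one row per
moth genus with at least one *sampled* species — sampled meaning at least
one wild record; species known only from captivity are excluded from all
DS2 statistics, since those columns describe natural environments — and 13
columns: sampled and checklist-total species numbers, totals (set unions
over sampled species) and averages (arithmetic means of per-species
counts) for plant genera/families/orders, and the genus PD score. Totals
are unions, never sums, so `avg ≤ total ≤ per-species sum` holds by
construction. Reals are written with 6 significant digits; undefined
values are empty cells. Rows sort by moth family, genus, species for
byte-stable output.

## The polyphagy PD score

Faith's PD of a tip set is computed in one postorder pass: for every edge,
count how many selected tips lie below it; the edge contributes its length
when that count is positive and — under the rootless convention — smaller
than the full selection. With the root included (the default, matching the
common default of community-phylogenetics software), a single-family
species scores its root-to-tip path length rather than zero; because the
convention is not universal, it is exposed as a config flag
(`include_root`) and both variants are tested. The score for a species
uses its wild plant-family list only, with gymnosperm families excluded
first (the angiosperm/gymnosperm divergence would swamp the branch-length
sum) and families absent from the supplied tree dropped with a warning and
recorded in the result, not raised as errors, since tree/name mismatches
are common in practice. A species with no usable family has an undefined
score; the genus score is the mean of its sampled species' defined scores
and is undefined for gymnosperm-only genera.

Any user-supplied dated Newick tree with family-level tip labels works; a
species-level tree can be collapsed to families by keeping the
lexicographically first tip per family (`collapse_to_families`). Branch
lengths are required and must be non-negative; a root-edge length, if
present, is never counted.

Correctness is established two independent ways: a brute-force oracle
(`pd_bruteforce`) that enumerates each tip's rootward path as an explicit
edge set, unions them and — for the rootless case — finds the MRCA by
exhaustive ancestor-set intersection; and the `pd` function of the picante
R package, called through Rscript in one unit test. Agreement is exact to
floating-point rounding (observed ≤ 1e-12 absolute on trees of height
100); tests use 1e-9 relative tolerance.

## Synthetic data and what it shows

The generator emulates the structure of a real compilation: a plant
taxonomy of configurable size with a gymnosperm fraction, a moth checklist
across two families, per-species host sets drawn at species rank with a
shifted-Poisson breadth (1 + Poisson(mean − 1), so every species eats at
least one plant), records scattered over several sources with duplication,
a captivity flag applied per association, and name-variant noise
(formatting damage, author decorations, alias genera registered in the
synonym table). All draws flow from one seed; the noise stream is spawned
separately from the same seed so runs differing only in noise rate share
identical underlying associations — which makes the reconciliation
property exactly testable. A ledger of ground truth (per-species name sets
per rank and setting, per-species PD via the brute-force oracle, per-genus
DS2 values computed inline) is kept by direct bookkeeping, independent of
the pipeline code it validates.

Default study conditions: 40 plant families (8% gymnosperm), 120 plant
genera, 25 moth genera, 120 moth species, 3 sources, mean host breadth 3,
15% duplication, 10% captive records, 10% name noise — a deliberately
desk-scale version of a multi-source compilation. The dated tree is a
pure-birth (Yule, rate 1) tree rescaled to height 100 time units, with the
waiting time to the next unrealised birth appended to terminal branches so
the present-day tips have positive lengths; this is test scaffolding, not
a claim about angiosperm history.

What passing tests therefore show: the record algebra (merge, dedupe,
partition), the reconciliation machinery, the DS1/DS2 aggregation rules
and the PD computation are exactly correct under known truth, and robust
to the noise forms modelled. What they do not show: performance of the
normalizer on the full messiness of real nomenclature (handwritten
qualifiers, misspellings needing fuzzy matching), correctness of any
particular external taxonomy, or ecological realism of simulated host
choice (uniform over the plant pool, no biogeography or phenology).

## Numerical and degenerate-input choices

Floating-point comparisons in tests use 1e-9 relative tolerance. Empty
record inputs yield empty DS1/DS2 tables with full headers and exit
status 0. A moth species with zero records cannot be summarised (error);
an empty tip set is an error for PD; an unknown tip is an error for
`faith_pd` but a recorded drop at the `species_pd` level, where the caller
cannot control tree coverage. Ties in exemplar choice when collapsing
species-level trees are broken lexicographically. Zero-length branches are
legal. Output files are byte-deterministic given identical inputs and
config.

## Known limitations

- Published compilation-wide figures (total record counts per source
  database) depend on the original source databases, which this package
  does not acquire or redistribute; it reproduces the *mechanism* (the
  per-source audit accounting), not those numbers.
- Exact reproduction of name strings in deposited datasets is not
  guaranteed: the reconciliation mapping used to produce them is not
  public, and this package's normalizer is rule-based.
- Only Faith's PD is implemented; other diversity metrics (MPD, MNTD),
  branch-length rescaling and tree dating are out of scope.
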