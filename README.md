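# polyphagy

Tools for building global caterpillar food-plant datasets and quantifying
how polyphagous (generalist) moth caterpillars are, using phylogenetic
diversity of their food plants.

Knowledge of what caterpillars eat is scattered across large institutional
databases, rearing inventories and personal compilations that overlap,
duplicate each other and spell plant names inconsistently. This package is
for ecologists and systematists who need to merge such sources into one
qualitative dataset — the unit is the unique combination of caterpillar
species, plant identity and source, with captive/introduced records kept
apart from natural-environment records — and then summarise food-plant
breadth per moth species and genus, including a polyphagy score with a
phylogenetic meaning.

## The score

For a moth species $s$ with wild-recorded angiosperm plant-family set
$F_s$ on a dated family-level phylogeny $T$, the polyphagy score is
Faith's phylogenetic diversity

$$\mathrm{PD}(F_s) = \sum_{e \,\in\, \mathrm{paths}(F_s)} \ell_e,$$

the summed branch lengths of the union of root-to-tip paths of the tips in
$F_s$ (with the root included, the default; a rootless variant restricted
below the most recent common ancestor is also provided). Gymnosperm
families are excluded first — the deep angiosperm/gymnosperm split would
otherwise dominate the sum — and a species eating only gymnosperms has an
undefined score. Genus scores are arithmetic means of the defined species
scores. Two species each eating "two plant families" can thus differ
sharply: distantly related families imply a wider evolutionary menu than
two close relatives.

## Worked example

```python
from polyphagy import PlantLookup, faith_pd, parse_newick

tree = parse_newick(
    "((Fagaceae:60,Salicaceae:60):40,(Solanaceae:80,Rubiaceae:80):20);"
)
close = {"Fagaceae", "Salicaceae"}   # two related rosid families
far = {"Fagaceae", "Solanaceae"}     # rosid + asterid
print(faith_pd(tree, close), faith_pd(tree, far))
```

prints `160.0 200.0`: both caterpillars eat two families, but the one
spanning the rosid/asterid split connects 200 Myr of branch length against
160 for the pair of relatives, so it is scored as more polyphagous.

The full pipeline is driven by a YAML config (or the `polyphagy` CLI:
`simulate`, `build`, `pd`, `validate`). On a simulated three-source bundle:

```python
from polyphagy import SimConfig, simulate_dataset, write_dataset
from polyphagy.pipeline import PipelineConfig, run_build

paths = write_dataset(simulate_dataset(SimConfig(seed=42)), "bundle/")
result = run_build(PipelineConfig.from_yaml(paths["config"]))
print(result.audit["records_merged"], result.audit["records_after_dedupe"])
print(len(result.ds1), len(result.ds2))
```

prints `420 401` and `120 25`: 420 records read across the three sources
collapse to 401 unique (moth, plant, source, setting) records, summarised
into a 120-row per-species table (DS1, 21 columns: counts and name lists
of plant genera/species/families/orders, wild and captive separately) and
a 25-row per-genus table (DS2, 13 columns: sampling coverage against the
checklist, totals and averages of wild plant-taxon counts, and the
`PD_score` column, e.g. 259.4 time units for the first genus — the mean
summed branch length connecting the angiosperm families its species eat).

The `examples/` directory has one short narrative script per capability:
dataset building, PD scoring, and name reconciliation/deduplication.

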