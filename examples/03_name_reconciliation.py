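"""Reconcile messy plant-name strings and deduplicate records.

Source databases write the same plant many ways: extra whitespace, author
citations, open nomenclature ("sp.", "cf."), synonyms. Normalization plus
a local synonym table maps them all to one accepted lineage, after which
deduplication keeps one record per (moth, plant, source, setting) key.
"""

from polyphagy import (
    FoodPlantRecord,
    PlantLookup,
    RecordTable,
    SourceTag,
    dedupe_records,
    normalize_name,
    resolve_plant,
)
from polyphagy.records import resolve_records

lookup = PlantLookup(
    genus_to_family={"Quercus": "Fagaceae"},
    family_to_order={"Fagaceae": "Fagales"},
    family_to_group={"Fagaceae": "angiosperm"},
    synonyms={"Qercus": "Quercus"},
)

for raw in ["  quercus   robur L. ", "Quercus sp.", "Prunus cf. avium",
            "Quercus robur var. pedunculata"]:
    norm = normalize_name(raw)
    print(f"{raw!r:42} -> {norm.name!r}"
          + ("  [genus only]" if norm.genus_only else ""))

print()
variants = ["Quercus robur", "quercus robur L.", "Qercus robur", "Quercus sp."]
for raw in variants:
    lineage = resolve_plant(raw, lookup)
    print(f"{raw!r:20} resolves to {lineage}")

table = RecordTable(
    [FoodPlantRecord("Actias luna", raw, "HOSTS", "wild") for raw in variants],
    [SourceTag("HOSTS")],
)
resolved, unresolved, _ = resolve_records(table, lookup, {})
deduped = dedupe_records(resolved)
print(f"\n{len(table)} raw records -> {len(deduped)} after reconciliation + dedup")
print("(three spellings of Quercus robur collapse; the genus-only record",
      "'Quercus sp.' stays distinct because it carries less information)")
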