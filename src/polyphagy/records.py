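"""Reading, merging, deduplicating and partitioning food-plant association
records.

A record is one source observation of a caterpillar feeding on a plant:
the unit of the combined dataset is the unique combination of caterpillar
species, plant identity and source (plus the wild/captive setting, which
downstream tables report separately). The dataset is qualitative — the
frequency of records carries no meaning — so deduplication keeps the first
occurrence of each key and nothing counts how often a key was seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .taxonomy import PlantLineage, normalize_name

logger = logging.getLogger(__name__)

WILD = "wild"
CAPTIVE = "captive_or_introduced"

_SETTING_ALIASES = {
    "wild": WILD,
    "natural": WILD,
    "in natura": WILD,
    "captive": CAPTIVE,
    "captive_or_introduced": CAPTIVE,
    "captivity": CAPTIVE,
    "introduced": CAPTIVE,
    "rearing": CAPTIVE,
    "capt": CAPTIVE,
}

_TRUTHY = {"true", "1", "yes", "y", "t"}

#: fixed column order of written record tables
RECORD_COLUMNS = [
    "moth_family",
    "moth_genus",
    "moth_species",
    "plant_name_raw",
    "plant_genus",
    "plant_species",
    "plant_family",
    "plant_order",
    "plant_group",
    "source",
    "setting",
]


class SchemaError(ValueError):
    """An input table does not match the expected schema."""


@dataclass(frozen=True)
class SourceTag:
    """Identity of one contributing database (e.g. "HOSTS", "DHJ", "JH")."""

    id: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SourceTag id must be non-empty")


@dataclass
class FoodPlantRecord:
    moth_species: str
    plant_name_raw: str
    source: str
    setting: str
    questionable: bool = False
    moth_family: str = ""
    moth_subfamily: str = ""
    moth_tribe: str = ""
    plant: PlantLineage | None = None

    def __post_init__(self) -> None:
        if not self.plant_name_raw:
            raise ValueError("plant_name_raw must be non-empty")
        if self.setting not in (WILD, CAPTIVE):
            raise ValueError(f"setting must be {WILD!r} or {CAPTIVE!r}, got {self.setting!r}")

    @property
    def moth_genus(self) -> str:
        return self.moth_species.split(" ", 1)[0] if self.moth_species else ""

    def plant_key(self) -> tuple[str, str]:
        """Plant identity at the finest resolved rank.

        Species if resolved to species, else genus; unresolved names fall
        back to their normalized verbatim string so that distinct unresolved
        names never collapse.
        """
        if self.plant is not None:
            if self.plant.species:
                return ("species", self.plant.species)
            return ("genus", self.plant.genus)
        norm = normalize_name(self.plant_name_raw)
        return ("raw", norm.name if norm else self.plant_name_raw.strip().casefold())

    def key(self) -> tuple:
        """Deduplication key: (moth, plant identity, source, setting)."""
        return (self.moth_species, self.plant_key(), self.source, self.setting)


@dataclass
class RecordTable:
    """Ordered collection of records plus the provenance of their sources."""

    records: list[FoodPlantRecord] = field(default_factory=list)
    provenance: list[SourceTag] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FoodPlantRecord]:
        return iter(self.records)

    def source_ids(self) -> set[str]:
        return {t.id for t in self.provenance}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            p = r.plant
            rows.append(
                {
                    "moth_family": r.moth_family,
                    "moth_genus": r.moth_genus,
                    "moth_species": r.moth_species,
                    "plant_name_raw": r.plant_name_raw,
                    "plant_genus": p.genus if p else "",
                    "plant_species": (p.species or "") if p else "",
                    "plant_family": p.family if p else "",
                    "plant_order": p.order if p else "",
                    "plant_group": p.group if p else "",
                    "source": r.source,
                    "setting": r.setting,
                }
            )
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def parse_setting(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _SETTING_ALIASES:
        raise SchemaError(f"unrecognised setting value {value!r}")
    return _SETTING_ALIASES[key]


#: canonical field -> default column name in input tables
DEFAULT_MAPPING = {
    "moth_species": "moth_species",
    "plant_name": "plant_name",
    "source": "source",
    "setting": "setting",
    "questionable": "questionable",
    "moth_family": "moth_family",
}

_LINEAGE_COLUMNS = ("plant_genus", "plant_species", "plant_family", "plant_order", "plant_group")


def read_record_table(
    path: str | Path,
    dialect: str | None = None,
    mapping: Mapping[str, str] | None = None,
    source: SourceTag | None = None,
) -> RecordTable:
    """Read one source's record table from CSV, TSV or XLSX.

    ``mapping`` maps the canonical fields (moth_species, plant_name,
    setting, source, questionable, moth_family) to this source's column
    names; unmapped fields use the canonical name itself. The source may
    come from a column or from the ``source`` tag applied to every row.
    Verbatim plant names and row order are preserved.
    """
    path = Path(path)
    if dialect is None:
        dialect = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".xlsx": "xlsx"}.get(
            path.suffix.lower(), "csv"
        )
    try:
        if dialect == "xlsx":
            frame = pd.read_excel(path, dtype=str, engine="openpyxl")
        else:
            frame = pd.read_csv(path, dtype=str, sep="\t" if dialect == "tsv" else ",")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise OSError(f"could not read record table {path}: {exc}") from exc
    frame = frame.fillna("")

    colmap = dict(DEFAULT_MAPPING)
    if mapping:
        colmap.update(mapping)

    for required in ("moth_species", "plant_name", "setting"):
        if colmap[required] not in frame.columns:
            raise SchemaError(
                f"{path.name}: required column {colmap[required]!r} (for {required}) not found"
            )
    source_col = colmap["source"] if colmap["source"] in frame.columns else None
    if source_col is None and source is None:
        raise SchemaError(
            f"{path.name}: no source column {colmap['source']!r} and no source tag given"
        )

    q_col = colmap["questionable"] if colmap["questionable"] in frame.columns else None
    fam_col = colmap["moth_family"] if colmap["moth_family"] in frame.columns else None
    has_lineage = all(c in frame.columns for c in _LINEAGE_COLUMNS)

    records: list[FoodPlantRecord] = []
    tags: dict[str, SourceTag] = {}
    if source is not None:
        tags[source.id] = source
    for row in frame.to_dict(orient="records"):
        get = lambda col: str(row.get(col, "")).strip()
        plant_raw = str(row.get(colmap["plant_name"], ""))
        if not plant_raw.strip():
            continue  # blank row
        src_id = get(source_col) if source_col else source.id
        if src_id not in tags:
            tags[src_id] = SourceTag(src_id)
        plant = None
        if has_lineage and get("plant_genus"):
            plant = PlantLineage(
                genus=get("plant_genus"),
                species=get("plant_species") or None,
                family=get("plant_family"),
                order=get("plant_order"),
                group=get("plant_group"),
            )
        records.append(
            FoodPlantRecord(
                moth_species=get(colmap["moth_species"]),
                plant_name_raw=plant_raw,
                source=src_id,
                setting=parse_setting(row.get(colmap["setting"], "")),
                questionable=get(q_col).lower() in _TRUTHY if q_col else False,
                moth_family=get(fam_col) if fam_col else "",
                plant=plant,
            )
        )
    provenance = sorted(tags.values(), key=lambda t: t.id)
    return RecordTable(records=records, provenance=provenance)


def merge_sources(tables: Iterable[RecordTable]) -> RecordTable:
    """Concatenate source tables, preserving source tags and row order.

    No deduplication happens here: the same caterpillar/plant pair reported
    by two sources is two records. Provenance is the union of the inputs;
    the same source id appearing with two different descriptions is a
    conflict.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("merge_sources needs at least one table")
    records: list[FoodPlantRecord] = []
    provenance: dict[str, SourceTag] = {}
    for table in tables:
        for tag in table.provenance:
            prior = provenance.get(tag.id)
            if prior is not None and prior.description and tag.description and prior.description != tag.description:
                raise ValueError(
                    f"conflicting descriptions for source {tag.id!r}: "
                    f"{prior.description!r} vs {tag.description!r}"
                )
            if prior is None or (not prior.description and tag.description):
                provenance[tag.id] = tag
        records.extend(table.records)
    return RecordTable(records=records, provenance=sorted(provenance.values(), key=lambda t: t.id))


def dedupe_records(table: RecordTable) -> RecordTable:
    """Keep one record per (moth, plant identity, source, setting) key.

    Plant identity is compared at the finest resolved rank, so a genus-only
    record stays distinct from any species-level record of that genus.
    First occurrence wins; output order is stable. Idempotent.
    """
    seen: set[tuple] = set()
    kept: list[FoodPlantRecord] = []
    for r in table.records:
        k = r.key()
        if k not in seen:
            seen.add(k)
            kept.append(r)
    dropped = len(table.records) - len(kept)
    if dropped:
        logger.info("dedupe_records: removed %d duplicate records", dropped)
    return RecordTable(records=kept, provenance=list(table.provenance))


def partition_by_setting(table: RecordTable) -> tuple[RecordTable, RecordTable]:
    """Split into (wild, captive-or-introduced) tables; sizes always sum."""
    wild = [r for r in table.records if r.setting == WILD]
    captive = [r for r in table.records if r.setting == CAPTIVE]
    prov = list(table.provenance)
    return (
        RecordTable(records=wild, provenance=list(prov)),
        RecordTable(records=captive, provenance=list(prov)),
    )


def drop_questionable(table: RecordTable) -> RecordTable:
    """Remove records flagged questionable at source; the count is logged."""
    kept = [r for r in table.records if not r.questionable]
    removed = len(table.records) - len(kept)
    if removed:
        logger.info("drop_questionable: removed %d flagged records", removed)
    return RecordTable(records=kept, provenance=list(table.provenance))


def resolve_records(
    table: RecordTable,
    lookup,
    checklist,
) -> tuple[RecordTable, list[str], list[str]]:
    """Resolve every record's plant lineage and moth higher ranks in place
    order; returns (table, unresolved_plant_names, unmatched_moth_genera).

    Unresolved plant names stay on their records (they are excluded from
    counts downstream, never silently dropped here).
    """
    from .taxonomy import resolve_moth, resolve_plant  # local import avoids cycle noise

    unresolved: list[str] = []
    unmatched_genera: set[str] = set()
    out: list[FoodPlantRecord] = []
    for r in table.records:
        family, subfamily, tribe, genus, species = resolve_moth(r.moth_species, checklist)
        if genus and not family:
            unmatched_genera.add(genus)
        plant = resolve_plant(r.plant_name_raw, lookup)
        if plant is None:
            unresolved.append(r.plant_name_raw)
        out.append(
            replace(
                r,
                moth_species=species or r.moth_species,
                moth_family=family or r.moth_family,
                moth_subfamily=subfamily,
                moth_tribe=tribe,
                plant=plant,
            )
        )
    return (
        RecordTable(records=out, provenance=list(table.provenance)),
        unresolved,
        sorted(unmatched_genera),
    )
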