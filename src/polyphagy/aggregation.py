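"""Per-species (DS1) and per-genus (DS2) food-plant breadth summaries.

DS1 has one row per moth species with at least one record and 21 columns:
moth taxonomy, then counts and alphabetical name lists of the plant genera,
species, families and orders eaten, separately for natural-environment
(wild) and captive/introduced records. DS2 has one row per moth genus with
at least one wild-sampled species and 13 columns: sampling coverage against
the checklist, totals (unions over species) and averages (means over
sampled species) of wild plant-taxon counts, and the genus polyphagy
PD score.

Counting is qualitative and distinct-name based. A record resolved only to
genus contributes to the genus/family/order lists but not to the species
list; unresolved names contribute nothing (they are reported upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .records import WILD, RecordTable
from .taxonomy import MothChecklistEntry

logger = logging.getLogger(__name__)

#: delimiter joining name lists in DS1/DS2 cells
NAME_DELIMITER = "; "

DS1_COLUMNS = [
    "Family",
    "Subfamily",
    "Tribe",
    "Moth_Genus_name",
    "Moth_Species_Name",
    "Number_PlantGenus",
    "Plant_GenusNames",
    "Number_PlantSpecies",
    "Plant_SpeciesNames",
    "Number_PlantFamily",
    "Plant_FamilyNames",
    "Number_PlantOrders",
    "Plant_OrderNames",
    "Number_PlantGenus_Capt",
    "Plant_GenusNames_Capt",
    "Number_PlantSpecies_Capt",
    "Plant_SpeciesNames_Capt",
    "Number_PlantFamily_Capt",
    "Plant_FamilyNames_Capt",
    "Number_PlantOrders_Capt",
    "Plant_OrderNames_Capt",
]

DS2_COLUMNS = [
    "Family",
    "Subfamily",
    "Tribe",
    "Moth_Genus_Name",
    "NumberSampledMothSpecies",
    "TotalMothSpecies",
    "TotalNumberGenus",
    "AverageNumberGenus",
    "TotalNumberFamilies",
    "AverageNumberFamilies",
    "TotalNumberOrders",
    "AverageNumberOrders",
    "PD_score",
]


def _joined(names: set[str]) -> str:
    return NAME_DELIMITER.join(sorted(names))


def format_real(x: float | None) -> str:
    """Real-valued output cells: 6 significant digits; undefined -> empty."""
    return "" if x is None else f"{x:.6g}"


@dataclass
class RankSets:
    """Distinct plant names eaten, per rank, within one setting."""

    genera: set[str] = field(default_factory=set)
    species: set[str] = field(default_factory=set)
    families: set[str] = field(default_factory=set)
    orders: set[str] = field(default_factory=set)
    n_records: int = 0

    def add(self, lineage) -> None:
        self.n_records += 1
        if lineage is None:
            return
        self.genera.add(lineage.genus)
        self.families.add(lineage.family)
        self.orders.add(lineage.order)
        if lineage.species:
            self.species.add(lineage.species)


@dataclass
class SpeciesSummary:
    """One DS1 row: plant breadth of a single moth species."""

    moth_family: str
    moth_subfamily: str
    moth_tribe: str
    moth_genus: str
    moth_species: str
    wild: RankSets = field(default_factory=RankSets)
    captive: RankSets = field(default_factory=RankSets)

    @property
    def is_sampled(self) -> bool:
        """Sampled means at least one natural-environment record."""
        return self.wild.n_records > 0

    def to_row(self) -> dict:
        w, c = self.wild, self.captive
        return {
            "Family": self.moth_family,
            "Subfamily": self.moth_subfamily,
            "Tribe": self.moth_tribe,
            "Moth_Genus_name": self.moth_genus,
            "Moth_Species_Name": self.moth_species,
            "Number_PlantGenus": len(w.genera),
            "Plant_GenusNames": _joined(w.genera),
            "Number_PlantSpecies": len(w.species),
            "Plant_SpeciesNames": _joined(w.species),
            "Number_PlantFamily": len(w.families),
            "Plant_FamilyNames": _joined(w.families),
            "Number_PlantOrders": len(w.orders),
            "Plant_OrderNames": _joined(w.orders),
            "Number_PlantGenus_Capt": len(c.genera),
            "Plant_GenusNames_Capt": _joined(c.genera),
            "Number_PlantSpecies_Capt": len(c.species),
            "Plant_SpeciesNames_Capt": _joined(c.species),
            "Number_PlantFamily_Capt": len(c.families),
            "Plant_FamilyNames_Capt": _joined(c.families),
            "Number_PlantOrders_Capt": len(c.orders),
            "Plant_OrderNames_Capt": _joined(c.orders),
        }


@dataclass
class GenusSummary:
    """One DS2 row: polyphagy of a moth genus over its sampled species."""

    moth_family: str
    moth_subfamily: str
    moth_tribe: str
    moth_genus: str
    n_sampled_species: int
    n_total_species: int | None
    total_plant_genera: int
    total_plant_families: int
    total_plant_orders: int
    avg_plant_genera: float
    avg_plant_families: float
    avg_plant_orders: float
    pd_score: float | None

    def to_row(self) -> dict:
        """Numeric row; undefined values are NaN and become empty cells
        when the table is written (reals at 6 significant digits)."""
        import numpy as np

        return {
            "Family": self.moth_family,
            "Subfamily": self.moth_subfamily,
            "Tribe": self.moth_tribe,
            "Moth_Genus_Name": self.moth_genus,
            "NumberSampledMothSpecies": self.n_sampled_species,
            "TotalMothSpecies": np.nan if self.n_total_species is None else self.n_total_species,
            "TotalNumberGenus": self.total_plant_genera,
            "AverageNumberGenus": self.avg_plant_genera,
            "TotalNumberFamilies": self.total_plant_families,
            "AverageNumberFamilies": self.avg_plant_families,
            "TotalNumberOrders": self.total_plant_orders,
            "AverageNumberOrders": self.avg_plant_orders,
            "PD_score": np.nan if self.pd_score is None else self.pd_score,
        }


def summarize_species(
    records: RecordTable,
    moth_species: str,
    checklist: Mapping[str, MothChecklistEntry] | None = None,
) -> SpeciesSummary:
    """Summarise the (resolved, deduplicated) records of one moth species.

    Raises ValueError if the species has no records.
    """
    mine = [r for r in records if r.moth_species == moth_species]
    if not mine:
        raise ValueError(f"no records for moth species {moth_species!r}")
    first = mine[0]
    genus = first.moth_genus
    entry = checklist.get(genus) if checklist else None
    summary = SpeciesSummary(
        moth_family=entry.family if entry else first.moth_family,
        moth_subfamily=entry.subfamily if entry else first.moth_subfamily,
        moth_tribe=entry.tribe if entry else first.moth_tribe,
        moth_genus=genus,
        moth_species=moth_species,
    )
    for r in mine:
        bucket = summary.wild if r.setting == WILD else summary.captive
        bucket.add(r.plant)
    return summary


def species_summaries(
    records: RecordTable,
    checklist: Mapping[str, MothChecklistEntry] | None = None,
) -> list[SpeciesSummary]:
    """One summary per moth species with >=1 record, sorted by
    (family, genus, species) for stable output."""
    order: list[str] = []
    seen: set[str] = set()
    for r in records:
        if r.moth_species not in seen:
            seen.add(r.moth_species)
            order.append(r.moth_species)
    summaries = [summarize_species(records, sp, checklist) for sp in order]
    summaries.sort(key=lambda s: (s.moth_family, s.moth_genus, s.moth_species))
    return summaries


def summarize_genus(
    summaries: Sequence[SpeciesSummary],
    entry: MothChecklistEntry | None,
    pd_scores: Mapping[str, float | None],
) -> GenusSummary:
    """Aggregate one moth genus from its species summaries.

    Only species with at least one wild record count as sampled: totals are
    unions of their wild name sets, averages are means of their wild counts,
    and the genus PD score is the mean of their defined species PD scores.
    """
    if not summaries:
        raise ValueError("summarize_genus requires at least one species summary")
    genera = {s.moth_genus for s in summaries}
    if len(genera) != 1:
        raise ValueError(f"species summaries span several genera: {sorted(genera)}")
    sampled = [s for s in summaries if s.is_sampled]
    first = summaries[0]
    if entry is not None and entry.total_species < len(sampled):
        logger.warning(
            "genus %s: checklist total_species (%d) < sampled species (%d)",
            first.moth_genus, entry.total_species, len(sampled),
        )

    union_genera: set[str] = set()
    union_families: set[str] = set()
    union_orders: set[str] = set()
    for s in sampled:
        union_genera |= s.wild.genera
        union_families |= s.wild.families
        union_orders |= s.wild.orders
    n = len(sampled)
    mean = lambda xs: (float(sum(xs)) / n) if n else 0.0
    defined_pd = [
        pd_scores[s.moth_species]
        for s in sampled
        if pd_scores.get(s.moth_species) is not None
    ]
    return GenusSummary(
        moth_family=entry.family if entry else first.moth_family,
        moth_subfamily=entry.subfamily if entry else first.moth_subfamily,
        moth_tribe=entry.tribe if entry else first.moth_tribe,
        moth_genus=first.moth_genus,
        n_sampled_species=n,
        n_total_species=entry.total_species if entry else None,
        total_plant_genera=len(union_genera),
        total_plant_families=len(union_families),
        total_plant_orders=len(union_orders),
        avg_plant_genera=mean([len(s.wild.genera) for s in sampled]),
        avg_plant_families=mean([len(s.wild.families) for s in sampled]),
        avg_plant_orders=mean([len(s.wild.orders) for s in sampled]),
        pd_score=(float(sum(defined_pd)) / len(defined_pd)) if defined_pd else None,
    )


def build_ds1(
    records: RecordTable,
    checklist: Mapping[str, MothChecklistEntry] | None = None,
) -> pd.DataFrame:
    """The per-species table: one row per moth species with >=1 record,
    exactly the 21 schema columns, sorted by family, genus, species."""
    summaries = species_summaries(records, checklist)
    return summaries_to_ds1(summaries)


def summaries_to_ds1(summaries: Sequence[SpeciesSummary]) -> pd.DataFrame:
    rows = [s.to_row() for s in summaries]
    return pd.DataFrame(rows, columns=DS1_COLUMNS)


def build_ds2(
    summaries: Sequence[SpeciesSummary],
    checklist: Mapping[str, MothChecklistEntry],
    pd_scores: Mapping[str, float | None],
) -> pd.DataFrame:
    """The per-genus table: one row per moth genus with >=1 sampled species,
    exactly the 13 schema columns. A genus absent from the checklist gets a
    blank TotalMothSpecies and a warning."""
    by_genus: dict[str, list[SpeciesSummary]] = {}
    for s in summaries:
        by_genus.setdefault(s.moth_genus, []).append(s)
    rows = []
    for genus in sorted(by_genus, key=lambda g: (by_genus[g][0].moth_family, g)):
        group = by_genus[genus]
        if not any(s.is_sampled for s in group):
            continue
        entry = checklist.get(genus)
        if entry is None:
            logger.warning("genus %s missing from checklist; TotalMothSpecies left blank", genus)
        rows.append(summarize_genus(group, entry, pd_scores).to_row())
    frame = pd.DataFrame(rows, columns=DS2_COLUMNS)
    if len(frame):
        frame["TotalMothSpecies"] = frame["TotalMothSpecies"].astype("Int64")
    return frame


def write_ds2(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a DS2 table: reals at 6 significant digits, NaN -> empty."""
    frame.to_csv(path, index=False, float_format="%.6g")


# -- reading back / validating written tables -----------------------------

def read_ds1(path: str | Path) -> pd.DataFrame:
    """Read a per-species (DS1) table from CSV or XLSX and validate its
    21-column schema; raises ValueError naming any missing column."""
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        frame = pd.read_excel(path, dtype=str, engine="openpyxl")
    else:
        frame = pd.read_csv(path, dtype=str)
    frame = frame.fillna("")
    missing = [c for c in DS1_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"DS1 table missing columns: {missing}")
    return frame


def read_ds2(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        frame = pd.read_excel(path, dtype=str, engine="openpyxl")
    else:
        frame = pd.read_csv(path, dtype=str)
    frame = frame.fillna("")
    missing = [c for c in DS2_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"DS2 table missing columns: {missing}")
    return frame


def split_names(cell: str) -> list[str]:
    """Split a DS1/DS2 name-list cell back into names."""
    cell = str(cell).strip()
    if not cell:
        return []
    return [n.strip() for n in cell.split(NAME_DELIMITER.strip()) if n.strip()]


def count_species_genera_per_family(ds1: pd.DataFrame) -> pd.DataFrame:
    """Distinct moth species and genus counts per moth family in a DS1
    table — the headline coverage figures of a compilation."""
    out = (
        ds1.groupby("Family")
        .agg(
            n_species=("Moth_Species_Name", "nunique"),
            n_genera=("Moth_Genus_name", "nunique"),
        )
        .reset_index()
        .sort_values("Family")
        .reset_index(drop=True)
    )
    return out


def validate_ds1(frame: pd.DataFrame) -> list[str]:
    """Internal-consistency checks on a DS1 table; returns problems found."""
    problems: list[str] = []
    missing = [c for c in DS1_COLUMNS if c not in frame.columns]
    if missing:
        return [f"missing columns: {missing}"]
    pairs = [
        ("Number_PlantGenus", "Plant_GenusNames"),
        ("Number_PlantSpecies", "Plant_SpeciesNames"),
        ("Number_PlantFamily", "Plant_FamilyNames"),
        ("Number_PlantOrders", "Plant_OrderNames"),
        ("Number_PlantGenus_Capt", "Plant_GenusNames_Capt"),
        ("Number_PlantSpecies_Capt", "Plant_SpeciesNames_Capt"),
        ("Number_PlantFamily_Capt", "Plant_FamilyNames_Capt"),
        ("Number_PlantOrders_Capt", "Plant_OrderNames_Capt"),
    ]
    for i, row in frame.iterrows():
        for ncol, lcol in pairs:
            n = int(float(row[ncol])) if str(row[ncol]).strip() else 0
            if n != len(split_names(row[lcol])):
                problems.append(f"row {i}: {ncol}={n} != |{lcol}|={len(split_names(row[lcol]))}")
        for lo, hi, suffix in (
            ("Number_PlantFamily", "Number_PlantGenus", ""),
            ("Number_PlantOrders", "Number_PlantFamily", ""),
            ("Number_PlantFamily_Capt", "Number_PlantGenus_Capt", "_Capt"),
            ("Number_PlantOrders_Capt", "Number_PlantFamily_Capt", "_Capt"),
        ):
            if int(float(row[lo] or 0)) > int(float(row[hi] or 0)):
                problems.append(f"row {i}: {lo} > {hi}")
    return problems


def validate_ds2(frame: pd.DataFrame) -> list[str]:
    """Internal-consistency checks on a DS2 table; returns problems found."""
    problems: list[str] = []
    missing = [c for c in DS2_COLUMNS if c not in frame.columns]
    if missing:
        return [f"missing columns: {missing}"]
    for i, row in frame.iterrows():
        for avg_col, tot_col in (
            ("AverageNumberGenus", "TotalNumberGenus"),
            ("AverageNumberFamilies", "TotalNumberFamilies"),
            ("AverageNumberOrders", "TotalNumberOrders"),
        ):
            avg = float(row[avg_col]) if str(row[avg_col]).strip() else 0.0
            tot = float(row[tot_col]) if str(row[tot_col]).strip() else 0.0
            if avg > tot + 1e-9:
                problems.append(f"row {i}: {avg_col} > {tot_col}")
        if str(row["TotalMothSpecies"]).strip():
            if int(float(row["NumberSampledMothSpecies"])) > int(float(row["TotalMothSpecies"])):
                problems.append(f"row {i}: sampled species exceed checklist total")
    return problems
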