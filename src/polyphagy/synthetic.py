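"""Synthetic food-plant datasets with known ground truth.

Real compilations of caterpillar food plants are built from several
overlapping databases with duplicated records, captivity rearing records,
and inconsistent plant-name spellings. This module generates all pipeline
inputs — multi-source record tables, a plant lookup with synonyms, a moth
checklist and a dated (ultrametric) plant-family tree — while keeping an
independent ledger of what each moth species truly eats, so every pipeline
stage can be checked against exact expected output.

Truth values are computed by direct bookkeeping at generation time: set
unions and means written out inline, and phylogenetic diversity via the
explicit path-union oracle ``pd_bruteforce``. None of it goes through the
pipeline's own aggregation or PD code.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .aggregation import DS1_COLUMNS, DS2_COLUMNS, NAME_DELIMITER
from .records import CAPTIVE, WILD, FoodPlantRecord, RecordTable, SourceTag
from .taxonomy import ANGIOSPERM, GYMNOSPERM, MothChecklistEntry, PlantLookup, checklist_frame

TREE_HEIGHT = 100.0  # time units; dated trees are rescaled to this root age


# -- tree simulation -------------------------------------------------------

def simulate_tree(
    n_tips: int,
    seed: int,
    labels: Sequence[str] | None = None,
    height: float = TREE_HEIGHT,
) -> dendropy.Tree:
    """Random rooted binary ultrametric tree via a pure-birth (Yule)
    process, rescaled to the given root height.

    Tips are labelled Family0001, Family0002, ... unless explicit labels
    are supplied. Deterministic given the seed.
    """
    if n_tips < 2:
        raise ValueError("simulate_tree requires n_tips >= 2")
    if labels is not None and len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    tree.seed_node.edge.length = None
    # the process stops exactly at the n-th birth; observe the tree after
    # the waiting time to the next (unrealised) birth so terminal branches
    # at the present are positive
    extra = rng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    root_height = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    scale = height / root_height if root_height > 0 else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    leaves = list(tree.leaf_node_iter())
    names = list(labels) if labels is not None else [f"Family{i + 1:04d}" for i in range(n_tips)]
    for leaf, name in zip(leaves, names):
        leaf.taxon.label = name
    return tree


# -- brute-force PD oracle -------------------------------------------------

def pd_bruteforce(tree: dendropy.Tree, tips: Iterable[str], include_root: bool = True) -> float:
    """Faith's PD by explicit enumeration, for use as an independent oracle.

    Builds each selected tip's rootward path as a set of edge identities,
    unions them and sums branch lengths. For the rootless convention the
    most recent common ancestor is found by exhaustive ancestor-set
    intersection and the edges above it are subtracted.
    """
    wanted = set(tips)
    if not wanted:
        raise ValueError("pd_bruteforce requires a non-empty tip set")
    leaf_by_label = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter() if leaf.taxon is not None
    }
    unknown = wanted - set(leaf_by_label)
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)}")

    def rootward_edges(node):
        edges = []
        while node is not tree.seed_node:
            edges.append(node.edge)
            node = node.parent_node
        return edges

    union: dict[int, float] = {}
    ancestor_sets = []
    for label in sorted(wanted):
        node = leaf_by_label[label]
        ancestors = set()
        cur = node
        while cur is not None:
            ancestors.add(id(cur))
            cur = cur.parent_node
        ancestor_sets.append(ancestors)
        for edge in rootward_edges(node):
            union[id(edge)] = edge.length or 0.0

    excluded: set[int] = set()
    if not include_root:
        common = set.intersection(*ancestor_sets)
        # MRCA = the common ancestor farthest from the root
        mrca = None
        best_depth = -1
        for node in tree.preorder_node_iter():
            if id(node) in common:
                depth = 0
                cur = node
                while cur.parent_node is not None:
                    depth += 1
                    cur = cur.parent_node
                if depth > best_depth:
                    best_depth = depth
                    mrca = node
        cur = mrca
        while cur is not tree.seed_node:
            excluded.add(id(cur.edge))
            cur = cur.parent_node
    return float(sum(v for k, v in union.items() if k not in excluded))


# -- dataset simulation ----------------------------------------------------

@dataclass
class SimConfig:
    """Shape of a synthetic study.

    Defaults mirror a realistic desk-scale compilation: three overlapping
    sources, a few plant species per caterpillar on average with a skewed
    (shifted-Poisson) breadth distribution, about one record in ten from
    captivity, a small gymnosperm share of plant families, and occasional
    name-variant noise that a complete synonym table can reconcile.
    """

    n_plant_families: int = 40
    n_plant_genera: int = 120
    n_moth_genera: int = 25
    n_moth_species: int = 120
    n_sources: int = 3
    host_breadth_mean: float = 3.0
    duplicate_rate: float = 0.15
    captive_rate: float = 0.10
    gymnosperm_fraction: float = 0.08
    synonym_noise_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_plant_families", "n_plant_genera", "n_moth_genera", "n_moth_species", "n_sources"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_plant_genera < self.n_plant_families:
            raise ValueError("n_plant_genera must be >= n_plant_families")
        for name in ("duplicate_rate", "captive_rate", "gymnosperm_fraction", "synonym_noise_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.host_breadth_mean < 1.0:
            raise ValueError("host_breadth_mean must be >= 1 (every species eats something)")


@dataclass
class SpeciesTruth:
    moth_family: str
    moth_subfamily: str
    moth_tribe: str
    moth_genus: str
    moth_species: str
    wild: dict[str, set] = field(default_factory=dict)
    captive: dict[str, set] = field(default_factory=dict)
    n_wild: int = 0
    n_captive: int = 0
    pd: float | None = None


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time, independent of the pipeline."""

    species: dict[str, SpeciesTruth]

    def to_ds1_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.species.values():
            row = {
                "Family": t.moth_family,
                "Subfamily": t.moth_subfamily,
                "Tribe": t.moth_tribe,
                "Moth_Genus_name": t.moth_genus,
                "Moth_Species_Name": t.moth_species,
            }
            for sets, suffix in ((t.wild, ""), (t.captive, "_Capt")):
                for rank, (ncol, lcol) in {
                    "genera": ("Number_PlantGenus", "Plant_GenusNames"),
                    "species": ("Number_PlantSpecies", "Plant_SpeciesNames"),
                    "families": ("Number_PlantFamily", "Plant_FamilyNames"),
                    "orders": ("Number_PlantOrders", "Plant_OrderNames"),
                }.items():
                    names = sets[rank]
                    row[ncol + suffix] = len(names)
                    row[lcol + suffix] = NAME_DELIMITER.join(sorted(names))
            rows.append(row)
        frame = pd.DataFrame(rows, columns=DS1_COLUMNS)
        return frame.sort_values(
            ["Family", "Moth_Genus_name", "Moth_Species_Name"]
        ).reset_index(drop=True)

    def to_ds2_frame(self, checklist: dict[str, MothChecklistEntry]) -> pd.DataFrame:
        """Numeric DS2 truth: averages and PD as floats (NaN when undefined)."""
        by_genus: dict[str, list[SpeciesTruth]] = {}
        for t in self.species.values():
            by_genus.setdefault(t.moth_genus, []).append(t)
        rows = []
        for genus, group in by_genus.items():
            sampled = [t for t in group if t.n_wild > 0]
            if not sampled:
                continue
            union = {rank: set() for rank in ("genera", "families", "orders")}
            for t in sampled:
                for rank in union:
                    union[rank] |= t.wild[rank]
            n = len(sampled)
            pds = [t.pd for t in sampled if t.pd is not None]
            entry = checklist.get(genus)
            rows.append(
                {
                    "Family": group[0].moth_family,
                    "Subfamily": group[0].moth_subfamily,
                    "Tribe": group[0].moth_tribe,
                    "Moth_Genus_Name": genus,
                    "NumberSampledMothSpecies": n,
                    "TotalMothSpecies": entry.total_species if entry else np.nan,
                    "TotalNumberGenus": len(union["genera"]),
                    "AverageNumberGenus": sum(len(t.wild["genera"]) for t in sampled) / n,
                    "TotalNumberFamilies": len(union["families"]),
                    "AverageNumberFamilies": sum(len(t.wild["families"]) for t in sampled) / n,
                    "TotalNumberOrders": len(union["orders"]),
                    "AverageNumberOrders": sum(len(t.wild["orders"]) for t in sampled) / n,
                    "PD_score": (sum(pds) / len(pds)) if pds else np.nan,
                }
            )
        frame = pd.DataFrame(rows, columns=DS2_COLUMNS)
        return frame.sort_values(["Family", "Moth_Genus_Name"]).reset_index(drop=True)


@dataclass
class SimulatedDataset:
    config: SimConfig
    sources: list[RecordTable]
    lookup: PlantLookup
    checklist: dict[str, MothChecklistEntry]
    tree: dendropy.Tree
    truth: SyntheticTruth


def _empty_rank_sets() -> dict[str, set]:
    return {"genera": set(), "species": set(), "families": set(), "orders": set()}


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a full input bundle plus ground truth.

    All structural draws flow from one seed; name-variant noise uses a
    stream spawned from the same seed, so two configs differing only in
    ``synonym_noise_rate`` describe the same underlying associations.
    """
    struct_ss, noise_ss = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(struct_ss)
    noise_rng = np.random.default_rng(noise_ss)

    # plant taxonomy -------------------------------------------------------
    n_fam = config.n_plant_families
    families = [f"Family{i + 1:04d}" for i in range(n_fam)]
    n_gym = int(round(config.gymnosperm_fraction * n_fam))
    gym_idx = set(rng.choice(n_fam, size=n_gym, replace=False).tolist()) if n_gym else set()
    family_order = {fam: f"Order{i // 3 + 1:03d}" for i, fam in enumerate(families)}
    family_group = {
        fam: (GYMNOSPERM if i in gym_idx else ANGIOSPERM) for i, fam in enumerate(families)
    }

    genera = [f"Pgenus{i + 1:04d}" for i in range(config.n_plant_genera)]
    genus_family: dict[str, str] = {}
    for i, genus in enumerate(genera):
        fam = families[i] if i < n_fam else families[int(rng.integers(n_fam))]
        genus_family[genus] = fam

    # every alias genus is registered up front: the synonym map is complete
    synonyms = {f"Syn{g.lower()}".capitalize(): g for g in genera}
    lookup = PlantLookup(
        genus_to_family=genus_family,
        family_to_order=family_order,
        family_to_group=family_group,
        synonyms=dict(synonyms),
    )

    plant_pool: list[str] = []  # accepted binomials
    for genus in genera:
        n_sp = 1 + int(rng.integers(3))
        for j in range(n_sp):
            plant_pool.append(f"{genus} x{chr(97 + j)}")

    # moth taxonomy --------------------------------------------------------
    moth_genera = [f"Mgenus{i + 1:03d}" for i in range(config.n_moth_genera)]
    moth_meta = {
        g: MothChecklistEntry(
            family="Saturniidae" if i % 2 == 0 else "Sphingidae",
            subfamily=f"Subfamily{i % 3 + 1}",
            tribe=f"Tribe{i % 5 + 1}",
            genus=g,
            total_species=1,  # fixed up below
        )
        for i, g in enumerate(moth_genera)
    }
    moth_species: list[str] = []
    species_genus: dict[str, str] = {}
    genus_counts = {g: 0 for g in moth_genera}
    for i in range(config.n_moth_species):
        g = moth_genera[int(rng.integers(config.n_moth_genera))]
        name = f"{g} m{i + 1:03d}"
        moth_species.append(name)
        species_genus[name] = g
        genus_counts[g] += 1
    checklist = {}
    for g, entry in moth_meta.items():
        total = max(1, genus_counts[g] + int(rng.poisson(2)))
        checklist[g] = MothChecklistEntry(
            entry.family, entry.subfamily, entry.tribe, g, total
        )

    # dated tree over angiosperm families ---------------------------------
    angio = sorted(f for f in families if family_group[f] == ANGIOSPERM)
    if len(angio) < 2:
        raise ValueError("need at least two angiosperm families for the tree")
    tree_seed = int(rng.integers(2**31))
    tree = simulate_tree(len(angio), tree_seed, labels=angio)

    # associations, records and truth -------------------------------------
    tags = [SourceTag(f"SRC{i + 1}", f"synthetic source {i + 1}") for i in range(config.n_sources)]
    per_source_rows: list[list[FoodPlantRecord]] = [[] for _ in tags]
    truth_species: dict[str, SpeciesTruth] = {}

    def noisy_name(genus: str, epithet: str) -> str:
        kind = int(noise_rng.integers(3))
        if kind == 0:
            return f"  {genus.upper()} {epithet}  L. "
        if kind == 1:
            alias = f"Syn{genus.lower()}".capitalize()
            return f"{alias} {epithet}"
        return f"{genus} {epithet} (Janz.) Sm."

    for moth in moth_species:
        g = species_genus[moth]
        meta = checklist[g]
        t = SpeciesTruth(
            moth_family=meta.family,
            moth_subfamily=meta.subfamily,
            moth_tribe=meta.tribe,
            moth_genus=g,
            moth_species=moth,
            wild=_empty_rank_sets(),
            captive=_empty_rank_sets(),
        )
        breadth = 1 + int(rng.poisson(config.host_breadth_mean - 1.0))
        breadth = min(breadth, len(plant_pool))
        hosts = [plant_pool[k] for k in rng.choice(len(plant_pool), size=breadth, replace=False)]
        for plant in sorted(hosts):
            genus, epithet = plant.split(" ", 1)
            fam = genus_family[genus]
            setting = CAPTIVE if rng.random() < config.captive_rate else WILD
            sets = t.captive if setting == CAPTIVE else t.wild
            sets["genera"].add(genus)
            sets["species"].add(plant)
            sets["families"].add(fam)
            sets["orders"].add(family_order[fam])
            if setting == CAPTIVE:
                t.n_captive += 1
            else:
                t.n_wild += 1

            source_idxs = [int(rng.integers(config.n_sources))]
            if rng.random() < config.duplicate_rate:
                source_idxs.append(int(rng.integers(config.n_sources)))
            for si in source_idxs:
                raw = plant
                if noise_rng.random() < config.synonym_noise_rate:
                    raw = noisy_name(genus, epithet)
                per_source_rows[si].append(
                    FoodPlantRecord(
                        moth_species=moth,
                        plant_name_raw=raw,
                        source=tags[si].id,
                        setting=setting,
                    )
                )
        wild_angio = {f for f in t.wild["families"] if family_group[f] == ANGIOSPERM}
        t.pd = pd_bruteforce(tree, wild_angio, include_root=True) if wild_angio else None
        truth_species[moth] = t

    sources = [
        RecordTable(records=rows, provenance=[tag])
        for rows, tag in zip(per_source_rows, tags)
    ]
    return SimulatedDataset(
        config=config,
        sources=sources,
        lookup=lookup,
        checklist=checklist,
        tree=tree,
        truth=SyntheticTruth(species=truth_species),
    )


# -- writing the bundle ----------------------------------------------------

def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the full input bundle (per-source record CSVs, lookup and
    synonym CSVs, checklist CSV, Newick tree, truth tables and a ready
    pipeline config) to a directory; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    source_entries = []
    for table in ds.sources:
        tag = table.provenance[0]
        p = outdir / f"records_{tag.id}.csv"
        rows = [
            {
                "moth_species": r.moth_species,
                "plant_name": r.plant_name_raw,
                "source": r.source,
                "setting": r.setting,
                "questionable": str(r.questionable).lower(),
            }
            for r in table.records
        ]
        pd.DataFrame(
            rows, columns=["moth_species", "plant_name", "source", "setting", "questionable"]
        ).to_csv(p, index=False)
        paths[f"records_{tag.id}"] = p
        source_entries.append({"path": p.name, "id": tag.id, "description": tag.description})

    paths["lookup"] = outdir / "lookup.csv"
    ds.lookup.to_frame().to_csv(paths["lookup"], index=False)
    paths["synonyms"] = outdir / "synonyms.csv"
    ds.lookup.synonyms_frame().to_csv(paths["synonyms"], index=False)
    paths["checklist"] = outdir / "checklist.csv"
    checklist_frame(ds.checklist).to_csv(paths["checklist"], index=False)
    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(
        ds.tree.as_string(schema="newick", suppress_rooting=True)
    )
    paths["truth_ds1"] = outdir / "truth_ds1.csv"
    ds.truth.to_ds1_frame().to_csv(paths["truth_ds1"], index=False)
    paths["truth_ds2"] = outdir / "truth_ds2.csv"
    ds.truth.to_ds2_frame(ds.checklist).to_csv(paths["truth_ds2"], index=False)

    config = {
        "sources": source_entries,
        "lookup": "lookup.csv",
        "synonyms": "synonyms.csv",
        "checklist": "checklist.csv",
        "tree": "tree.nwk",
        "include_root": True,
        "output_dir": "output",
    }
    paths["config"] = outdir / "pipeline.yaml"
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    return paths
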