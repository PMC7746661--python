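"""End-to-end orchestration: read -> resolve -> filter -> dedupe ->
summarise -> PD -> write, with a stage-stamped audit trail.

The audit dictionary records counts at every stage (records read per
source, questionable records removed, duplicates removed, unresolved
names, families missing from the tree, table sizes) so a run prints the
same kind of summary a data paper reports, and so the accounting can be
checked: what goes into a stage equals what comes out plus what was
dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import aggregation, phylodiversity, records, taxonomy
from .records import RecordTable, SourceTag

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SourceSpec:
    path: Path
    id: str
    description: str = ""
    dialect: str | None = None
    mapping: dict[str, str] | None = None


@dataclass
class PipelineConfig:
    sources: list[SourceSpec]
    lookup: Path
    checklist: Path
    tree: Path | None = None
    synonyms: Path | None = None
    include_root: bool = True
    output_dir: Path = Path("output")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        base = path.parent
        raw = yaml.safe_load(path.read_text()) or {}

        def resolve(p):
            return None if p in (None, "") else (base / p if not Path(p).is_absolute() else Path(p))

        sources = []
        for entry in raw.get("sources", []):
            sources.append(
                SourceSpec(
                    path=resolve(entry["path"]),
                    id=str(entry.get("id", Path(entry["path"]).stem)),
                    description=str(entry.get("description", "")),
                    dialect=entry.get("dialect"),
                    mapping=entry.get("mapping"),
                )
            )
        if not sources:
            raise PipelineError("stage 'config': no sources listed")
        for key in ("lookup", "checklist"):
            if not raw.get(key):
                raise PipelineError(f"stage 'config': missing required path {key!r}")
        return cls(
            sources=sources,
            lookup=resolve(raw["lookup"]),
            checklist=resolve(raw["checklist"]),
            tree=resolve(raw.get("tree")),
            synonyms=resolve(raw.get("synonyms")),
            include_root=bool(raw.get("include_root", True)),
            output_dir=resolve(raw.get("output_dir", "output")),
            log_level=str(raw.get("log_level", "INFO")),
        )


@dataclass
class BuildResult:
    ds1: pd.DataFrame
    ds2: pd.DataFrame
    species_pd: pd.DataFrame
    audit: dict
    ds1_path: Path | None = None
    ds2_path: Path | None = None
    species_pd_path: Path | None = None
    audit_path: Path | None = None


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


@_stage("read")
def _read_sources(config: PipelineConfig) -> tuple[list[RecordTable], dict]:
    tables = []
    per_source = {}
    for spec in config.sources:
        table = records.read_record_table(
            spec.path,
            dialect=spec.dialect,
            mapping=spec.mapping,
            source=SourceTag(spec.id, spec.description),
        )
        logger.info("read %d records from %s (%s)", len(table), spec.path.name, spec.id)
        per_source[spec.id] = len(table)
        tables.append(table)
    return tables, per_source


def run_build(config: PipelineConfig, write: bool = True) -> BuildResult:
    """Run the full dataset build; returns the DS1/DS2/PD tables and audit.

    With ``write=True`` the tables are written to ``config.output_dir`` as
    ds1.csv, ds2.csv, species_pd.csv and audit.json. Any stage failure
    raises PipelineError with a stage-named message.
    """
    audit: dict = {}

    tables, per_source = _read_sources(config)
    audit["records_read_per_source"] = per_source

    merged = _stage("merge")(records.merge_sources)(tables)
    audit["records_merged"] = len(merged)
    logger.info("merged: %d records from %d sources", len(merged), len(tables))

    lookup = _stage("lookup")(taxonomy.PlantLookup.read)(config.lookup, config.synonyms)
    checklist = _stage("checklist")(taxonomy.read_checklist)(config.checklist)

    resolved, unresolved_plants, unmatched_genera = _stage("resolve")(records.resolve_records)(
        merged, lookup, checklist
    )
    audit["unresolved_plant_names"] = sorted(set(unresolved_plants))
    audit["n_unresolved_plant_records"] = len(unresolved_plants)
    audit["unmatched_moth_genera"] = unmatched_genera
    if unresolved_plants:
        logger.warning(
            "%d records carry plant names that do not resolve (%d distinct)",
            len(unresolved_plants), len(set(unresolved_plants)),
        )

    vetted = _stage("questionable")(records.drop_questionable)(resolved)
    audit["questionable_removed"] = len(resolved) - len(vetted)
    audit["records_after_questionable"] = len(vetted)

    deduped = _stage("dedupe")(records.dedupe_records)(vetted)
    audit["duplicates_removed"] = len(vetted) - len(deduped)
    audit["records_after_dedupe"] = len(deduped)
    logger.info("deduplicated: %d unique records", len(deduped))

    wild, captive = _stage("partition")(records.partition_by_setting)(deduped)
    audit["wild_records"] = len(wild)
    audit["captive_records"] = len(captive)

    summaries = _stage("summarize")(aggregation.species_summaries)(deduped, checklist)
    audit["n_moth_species"] = len(summaries)
    audit["n_moth_genera"] = len({s.moth_genus for s in summaries})
    logger.info(
        "summarised %d moth species in %d genera",
        audit["n_moth_species"], audit["n_moth_genera"],
    )

    pd_scores: dict[str, float | None] = {}
    pd_rows = []
    missing_families: set[str] = set()
    if config.tree is not None:
        tree = _stage("tree")(phylodiversity.read_tree)(config.tree)
        for s in summaries:
            result = _stage("pd")(phylodiversity.species_pd)(
                s, tree, lookup, include_root=config.include_root
            )
            pd_scores[s.moth_species] = result.pd
            missing_families |= result.families_missing_from_tree
            pd_rows.append(
                {
                    "moth_species": s.moth_species,
                    "n_families_used": len(result.families_used),
                    "n_families_missing": len(result.families_missing_from_tree),
                    "pd": aggregation.format_real(result.pd),
                }
            )
    else:
        pd_scores = {s.moth_species: None for s in summaries}
    audit["species_with_pd"] = sum(1 for v in pd_scores.values() if v is not None)
    audit["families_missing_from_tree"] = sorted(missing_families)

    ds1 = _stage("ds1")(aggregation.summaries_to_ds1)(summaries)
    ds2 = _stage("ds2")(aggregation.build_ds2)(summaries, checklist, pd_scores)
    species_pd_frame = pd.DataFrame(
        pd_rows, columns=["moth_species", "n_families_used", "n_families_missing", "pd"]
    )
    audit["ds1_rows"] = len(ds1)
    audit["ds2_rows"] = len(ds2)

    result = BuildResult(ds1=ds1, ds2=ds2, species_pd=species_pd_frame, audit=audit)
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.ds1_path = outdir / "ds1.csv"
        result.ds2_path = outdir / "ds2.csv"
        result.species_pd_path = outdir / "species_pd.csv"
        result.audit_path = outdir / "audit.json"
        ds1.to_csv(result.ds1_path, index=False)
        aggregation.write_ds2(ds2, result.ds2_path)
        species_pd_frame.to_csv(result.species_pd_path, index=False)
        result.audit_path.write_text(json.dumps(audit, indent=2, sort_keys=True))
        logger.info("wrote outputs to %s", outdir)
    return result


def run_pd_only(
    ds1_path: str | Path,
    tree_path: str | Path,
    lookup: taxonomy.PlantLookup,
    include_root: bool = True,
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Compute per-species PD and genus PD scores from a DS1 file alone.

    The wild plant-family name lists in DS1 are the only input needed: no
    raw records are touched. Returns the per-species PD table and a
    genus -> mean-PD map (None where no species has a defined score).
    """
    ds1 = aggregation.read_ds1(ds1_path)
    tree = phylodiversity.read_tree(tree_path)
    rows = []
    per_genus: dict[str, list[float]] = {}
    genus_seen: list[str] = []
    for _, row in ds1.iterrows():
        families = aggregation.split_names(row["Plant_FamilyNames"])
        pd_val, used, missing = phylodiversity.pd_from_families(
            families, tree, lookup, include_root=include_root
        )
        rows.append(
            {
                "moth_species": row["Moth_Species_Name"],
                "n_families_used": len(used),
                "n_families_missing": len(missing),
                "pd": aggregation.format_real(pd_val),
            }
        )
        genus = row["Moth_Genus_name"]
        if genus not in per_genus:
            per_genus[genus] = []
            genus_seen.append(genus)
        if pd_val is not None:
            per_genus[genus].append(pd_val)
    frame = pd.DataFrame(
        rows, columns=["moth_species", "n_families_used", "n_families_missing", "pd"]
    )
    genus_scores = {
        g: (sum(v) / len(v) if v else None) for g, v in per_genus.items()
    }
    return frame, genus_scores
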