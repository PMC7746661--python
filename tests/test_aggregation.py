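"""Per-species (DS1) and per-genus (DS2) summary tables."""

import numpy as np
import pandas as pd
import pytest

from polyphagy import (
    CAPTIVE,
    DS1_COLUMNS,
    DS2_COLUMNS,
    build_ds1,
    build_ds2,
    species_summaries,
    summarize_genus,
    summarize_species,
)
from polyphagy.aggregation import split_names, validate_ds1, validate_ds2


def test_summarize_species_distinct_counting(table, rec):
    t = table(
        [
            rec("Actias luna", "Quercus robur"),
            rec("Actias luna", "Quercus ilex"),
            rec("Actias luna", "Salix alba"),
        ]
    )
    s = summarize_species(t, "Actias luna")
    assert len(s.wild.genera) == 2
    assert len(s.wild.species) == 3
    assert s.wild.families == {"Fagaceae", "Salicaceae"}
    assert len(s.wild.orders) == 2
    assert len(s.captive.genera) == 0


def test_summarize_species_genus_only_record(table, rec):
    s = summarize_species(table([rec("Actias luna", "Quercus sp.")]), "Actias luna")
    assert (len(s.wild.genera), len(s.wild.species)) == (1, 0)
    assert (len(s.wild.families), len(s.wild.orders)) == (1, 1)


def test_summarize_species_captive_only(table, rec):
    t = table([rec("Actias luna", "Quercus robur", setting=CAPTIVE)])
    s = summarize_species(t, "Actias luna")
    assert not s.is_sampled
    assert len(s.wild.genera) == 0
    assert s.captive.species == {"Quercus robur"}


def test_summarize_species_ignores_unresolved_names(table, rec):
    t = table([rec("Actias luna", "Xyzus blah"), rec("Actias luna", "Quercus robur")])
    s = summarize_species(t, "Actias luna")
    assert s.wild.genera == {"Quercus"}
    assert s.wild.n_records == 2  # retained in the record count, not the name sets


def test_summarize_species_without_records_raises(table):
    with pytest.raises(ValueError, match="no records"):
        summarize_species(table([]), "Actias luna")


def test_summarize_genus_union_and_mean(table, rec, checklist):
    t = table(
        [
            rec("Actias luna", "Quercus robur"),
            rec("Actias luna", "Salix alba"),
            rec("Actias selene", "Quercus ilex"),
        ]
    )
    summaries = [summarize_species(t, sp) for sp in ("Actias luna", "Actias selene")]
    g = summarize_genus(summaries, checklist["Actias"], {})
    assert g.total_plant_genera == 2
    assert g.avg_plant_genera == pytest.approx(1.5)
    assert (g.n_sampled_species, g.n_total_species) == (2, 30)
    assert g.avg_plant_genera <= g.total_plant_genera


def test_summarize_genus_pd_mean_skips_undefined(table, rec, checklist):
    t = table([rec("Actias luna", "Quercus robur"), rec("Actias selene", "Pinus nigra")])
    summaries = [summarize_species(t, sp) for sp in ("Actias luna", "Actias selene")]
    g = summarize_genus(summaries, checklist["Actias"], {"Actias luna": 10.0, "Actias selene": None})
    assert g.pd_score == pytest.approx(10.0)


def test_summarize_genus_excludes_captive_only_species(table, rec, checklist):
    t = table(
        [
            rec("Actias luna", "Quercus robur"),
            rec("Actias selene", "Salix alba", setting=CAPTIVE),
        ]
    )
    summaries = [summarize_species(t, sp) for sp in ("Actias luna", "Actias selene")]
    g = summarize_genus(summaries, checklist["Actias"], {})
    assert g.n_sampled_species == 1
    assert g.total_plant_genera == 1  # Salix, known only from captivity, not counted


def test_summarize_genus_empty_raises(checklist):
    with pytest.raises(ValueError):
        summarize_genus([], checklist["Actias"], {})


def test_build_ds1_shape_and_order(table, rec, checklist):
    t = table(
        [
            rec("Manduca sexta", "Salix alba"),
            rec("Actias luna", "Quercus robur"),
            rec("Actias luna", "Quercus ilex"),
        ]
    )
    ds1 = build_ds1(t, checklist)
    assert list(ds1.columns) == DS1_COLUMNS
    assert len(ds1.columns) == 21
    assert len(ds1) == 2
    # sorted by moth family, genus, species
    assert ds1["Moth_Species_Name"].tolist() == ["Actias luna", "Manduca sexta"]
    assert ds1.loc[0, "Number_PlantSpecies"] == 2
    assert ds1.loc[0, "Plant_SpeciesNames"] == "Quercus ilex; Quercus robur"


def test_build_ds1_empty_input(table, checklist):
    ds1 = build_ds1(table([]), checklist)
    assert list(ds1.columns) == DS1_COLUMNS
    assert len(ds1) == 0


def test_build_ds2_shape(table, rec, checklist):
    t = table(
        [
            rec("Actias luna", "Quercus robur"),
            rec("Manduca sexta", "Salix alba"),
            rec("Manduca quinquemaculata", "Salix alba"),
        ]
    )
    summaries = species_summaries(t, checklist)
    ds2 = build_ds2(summaries, checklist, {})
    assert list(ds2.columns) == DS2_COLUMNS
    assert len(ds2.columns) == 13
    assert len(ds2) == 2
    manduca = ds2[ds2["Moth_Genus_Name"] == "Manduca"].iloc[0]
    assert manduca["NumberSampledMothSpecies"] == 2
    assert manduca["TotalNumberGenus"] == 1


def test_build_ds2_gymnosperm_only_genus_has_empty_pd(table, rec, checklist, tmp_path):
    t = table([rec("Actias luna", "Pinus nigra")])
    summaries = species_summaries(t, checklist)
    ds2 = build_ds2(summaries, checklist, {"Actias luna": None})
    assert np.isnan(ds2.loc[0, "PD_score"])
    from polyphagy.aggregation import write_ds2

    p = tmp_path / "ds2.csv"
    write_ds2(ds2, p)
    assert pd.read_csv(p, dtype=str).fillna("").loc[0, "PD_score"] == ""


def test_build_ds2_single_species_genus_averages_equal_counts(table, rec, checklist):
    t = table([rec("Actias luna", "Quercus robur"), rec("Actias luna", "Salix alba")])
    ds2 = build_ds2(species_summaries(t, checklist), checklist, {})
    row = ds2.iloc[0]
    assert row["AverageNumberGenus"] == row["TotalNumberGenus"] == 2
    assert row["AverageNumberFamilies"] == row["TotalNumberFamilies"] == 2


def test_build_ds2_genus_missing_from_checklist_blank_total(table, rec, checklist, caplog):
    import logging

    t = table([rec("Nosuchus bogus", "Quercus robur")])
    summaries = species_summaries(t, checklist)
    with caplog.at_level(logging.WARNING):
        ds2 = build_ds2(summaries, checklist, {})
    assert len(ds2) == 1
    assert pd.isna(ds2.loc[0, "TotalMothSpecies"])
    assert "missing from checklist" in caplog.text


def test_ds1_regrouped_by_genus_equals_ds2(table, rec, checklist):
    """Recomputing genus rows from the written per-species table must give
    the same DS2 (pipeline self-consistency)."""
    t = table(
        [
            rec("Actias luna", "Quercus robur"),
            rec("Actias luna", "Salix alba"),
            rec("Actias selene", "Quercus ilex"),
            rec("Manduca sexta", "Populus alba", setting=CAPTIVE),
            rec("Manduca sexta", "Salix alba"),
        ]
    )
    summaries = species_summaries(t, checklist)
    ds1 = build_ds1(t, checklist)
    ds2 = build_ds2(summaries, checklist, {})

    regrouped = {}
    for _, row in ds1.iterrows():
        if int(row["Number_PlantGenus"]) + int(row["Number_PlantFamily"]) == 0 and not split_names(
            row["Plant_OrderNames"]
        ):
            wild_sampled = False
        else:
            wild_sampled = True
        g = regrouped.setdefault(
            row["Moth_Genus_name"],
            {"n": 0, "genera": set(), "families": set(), "orders": set(), "per": []},
        )
        if wild_sampled:
            g["n"] += 1
            g["genera"].update(split_names(row["Plant_GenusNames"]))
            g["families"].update(split_names(row["Plant_FamilyNames"]))
            g["orders"].update(split_names(row["Plant_OrderNames"]))
            g["per"].append(
                (
                    int(row["Number_PlantGenus"]),
                    int(row["Number_PlantFamily"]),
                    int(row["Number_PlantOrders"]),
                )
            )
    for _, row in ds2.iterrows():
        g = regrouped[row["Moth_Genus_Name"]]
        assert row["NumberSampledMothSpecies"] == g["n"]
        assert row["TotalNumberGenus"] == len(g["genera"])
        assert row["TotalNumberFamilies"] == len(g["families"])
        assert row["AverageNumberGenus"] == pytest.approx(
            sum(p[0] for p in g["per"]) / g["n"]
        )


def test_summary_invariants_on_random_data(tmp_path):
    """Count fields equal list lengths; families <= genera; orders <= families;
    genus averages <= totals <= per-species sums."""
    from helpers import build_from_simulation
    from polyphagy import SimConfig

    ds, result = build_from_simulation(SimConfig(seed=101, n_moth_species=60), tmp_path, write=False)
    assert validate_ds1(result.ds1) == []
    assert validate_ds2(result.ds2) == []
    for _, row in result.ds1.iterrows():
        assert int(row["Number_PlantFamily"]) <= int(row["Number_PlantGenus"])
        assert int(row["Number_PlantOrders"]) <= int(row["Number_PlantFamily"])
    # totals are unions, never exceeding the per-species sums
    per_species = {
        sp: truth for sp, truth in ds.truth.species.items()
    }
    for _, row in result.ds2.iterrows():
        genus = row["Moth_Genus_Name"]
        member_sum = sum(
            len(t.wild["genera"]) for t in per_species.values() if t.moth_genus == genus
        )
        assert row["TotalNumberGenus"] <= member_sum
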