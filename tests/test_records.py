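"""Record I/O, merging, deduplication and wild/captive partitioning."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyphagy import (
    CAPTIVE,
    WILD,
    FoodPlantRecord,
    RecordTable,
    SchemaError,
    SourceTag,
    dedupe_records,
    drop_questionable,
    merge_sources,
    partition_by_setting,
    read_record_table,
)
from polyphagy.records import resolve_records


def _write_csv(path, rows, columns, sep=","):
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, sep=sep)


COLUMNS = ["moth_species", "plant_name", "source", "setting"]
ROWS = [
    ["Actias luna", "Quercus robur", "HOSTS", "wild"],
    ["Actias luna", "Salix alba", "DHJ", "wild"],
    ["Manduca sexta", "Quercus ilex", "JH", "captive"],
]


@pytest.mark.parametrize("sep,dialect", [(",", "csv"), ("\t", "tsv")])
def test_read_record_table_parses_rows_verbatim(tmp_path, sep, dialect):
    p = tmp_path / f"records.{dialect}"
    _write_csv(p, ROWS, COLUMNS, sep=sep)
    table = read_record_table(p, dialect=dialect)
    assert len(table) == 3
    assert [r.plant_name_raw for r in table] == ["Quercus robur", "Salix alba", "Quercus ilex"]
    assert [r.source for r in table] == ["HOSTS", "DHJ", "JH"]
    assert table.records[2].setting == CAPTIVE
    assert table.records[0].moth_genus == "Actias"


def test_read_record_table_xlsx(tmp_path):
    p = tmp_path / "records.xlsx"
    pd.DataFrame(ROWS, columns=COLUMNS).to_excel(p, index=False)
    table = read_record_table(p)
    assert len(table) == 3


def test_read_header_only_gives_empty_table(tmp_path):
    p = tmp_path / "empty.csv"
    _write_csv(p, [], COLUMNS)
    table = read_record_table(p, source=SourceTag("X"))
    assert len(table) == 0


def test_read_missing_plant_column_is_schema_error(tmp_path):
    p = tmp_path / "bad.csv"
    _write_csv(p, [["Actias luna", "HOSTS", "wild"]], ["moth_species", "source", "setting"])
    with pytest.raises(SchemaError, match="plant_name"):
        read_record_table(p)


def test_read_with_column_mapping(tmp_path):
    p = tmp_path / "mapped.csv"
    _write_csv(
        p,
        [["Actias luna", "Quercus robur", "natural"]],
        ["Moth", "FoodPlant", "Env"],
    )
    table = read_record_table(
        p,
        mapping={"moth_species": "Moth", "plant_name": "FoodPlant", "setting": "Env"},
        source=SourceTag("HOSTS", "host records"),
    )
    assert len(table) == 1
    assert table.records[0].setting == WILD
    assert table.records[0].source == "HOSTS"


def test_read_unreadable_file_is_io_error(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_record_table(tmp_path / "nope.csv")


def test_merge_concatenates_and_unions_provenance(table, rec):
    t1 = table([rec("Actias luna", "Quercus robur"), rec("Actias luna", "Salix alba")], ["HOSTS"])
    t2 = table(
        [
            rec("Manduca sexta", "Quercus ilex", source="JH"),
            rec("Manduca sexta", "Salix alba", source="JH"),
            rec("Actias luna", "Fagus sylvatica", source="JH"),
        ],
        ["JH"],
    )
    merged = merge_sources([t1, t2])
    assert len(merged) == 5
    assert merged.source_ids() == {"HOSTS", "JH"}


def test_merge_keeps_same_pair_from_two_sources(table, rec):
    # the record unit includes the source, so this is two records
    t1 = table([rec("Actias luna", "Quercus robur", source="HOSTS")], ["HOSTS"])
    t2 = table([rec("Actias luna", "Quercus robur", source="JH")], ["JH"])
    merged = dedupe_records(merge_sources([t1, t2]))
    assert len(merged) == 2


def test_merge_with_empty_is_identity(table, rec):
    t = table([rec("Actias luna", "Quercus robur")])
    empty = RecordTable(records=[], provenance=[])
    assert merge_sources([t, empty]).records == t.records


def test_merge_conflicting_source_descriptions_raises(table, rec):
    t1 = RecordTable([rec("Actias luna", "Quercus robur")], [SourceTag("H", "one database")])
    t2 = RecordTable([rec("Manduca sexta", "Salix alba", source="H")], [SourceTag("H", "another")])
    with pytest.raises(ValueError, match="conflicting"):
        merge_sources([t1, t2])


def test_merge_is_associative_up_to_order(table, rec):
    ts = [
        table([rec("Actias luna", "Quercus robur")], ["A"]),
        table([rec("Manduca sexta", "Salix alba", source="B")], ["B"]),
        table([rec("Actias luna", "Pinus nigra", source="C")], ["C"]),
    ]
    left = merge_sources([merge_sources(ts[:2]), ts[2]])
    right = merge_sources([ts[0], merge_sources(ts[1:])])
    assert {r.key() for r in left} == {r.key() for r in right}
    assert left.source_ids() == right.source_ids()


def test_dedupe_removes_exact_duplicates(table, rec):
    t = table([rec("Actias luna", "Quercus robur"), rec("Actias luna", "Quercus robur")])
    assert len(dedupe_records(t)) == 1


def test_dedupe_key_includes_source_and_setting(table, rec):
    t = table(
        [
            rec("Actias luna", "Quercus robur", source="HOSTS"),
            rec("Actias luna", "Quercus robur", source="JH"),
            rec("Actias luna", "Quercus robur", source="HOSTS", setting=CAPTIVE),
        ]
    )
    assert len(dedupe_records(t)) == 3


def test_dedupe_distinguishes_genus_only_from_species_level(table, rec):
    # "Quercus sp." resolves to genus rank: not the same key as a species record
    t = table([rec("Actias luna", "Quercus robur"), rec("Actias luna", "Quercus sp.")])
    assert len(dedupe_records(t)) == 2


def test_dedupe_collapses_name_variants_of_one_plant(table, rec):
    t = table([rec("Actias luna", "Quercus robur"), rec("Actias luna", "  quercus   robur L. ")])
    assert len(dedupe_records(t)) == 1


def test_dedupe_is_idempotent(table, rec):
    t = table(
        [rec("Actias luna", "Quercus robur"), rec("Actias luna", "Quercus robur"),
         rec("Actias luna", "Salix alba")]
    )
    once = dedupe_records(t)
    twice = dedupe_records(once)
    assert [r.key() for r in once.records] == [r.key() for r in twice.records]


def test_partition_splits_by_setting(table, rec):
    t = table(
        [rec("Actias luna", "Quercus robur"), rec("Actias luna", "Salix alba"),
         rec("Actias luna", "Fagus sylvatica"),
         rec("Actias luna", "Pinus nigra", setting=CAPTIVE),
         rec("Actias luna", "Populus alba", setting=CAPTIVE)]
    )
    wild, captive = partition_by_setting(t)
    assert (len(wild), len(captive)) == (3, 2)
    assert all(r.setting == WILD for r in wild)
    assert all(r.setting == CAPTIVE for r in captive)
    assert wild.source_ids() == captive.source_ids() == {"HOSTS"}


def test_partition_of_empty_table(table):
    wild, captive = partition_by_setting(table([]))
    assert (len(wild), len(captive)) == (0, 0)


def test_drop_questionable(table, rec):
    t = table(
        [rec("Actias luna", "Quercus robur"),
         rec("Actias luna", "Salix alba", questionable=True)]
        + [rec("Actias luna", f"Fagus sp{i}", resolve=False) for i in range(3)]
    )
    kept = drop_questionable(t)
    assert len(kept) == 4
    assert drop_questionable(kept).records == kept.records  # none flagged -> identity
    all_flagged = table([rec("Actias luna", "Quercus robur", questionable=True)])
    assert len(drop_questionable(all_flagged)) == 0


records_strategy = st.lists(
    st.builds(
        FoodPlantRecord,
        moth_species=st.sampled_from(["Actias luna", "Manduca sexta", "Actias selene"]),
        plant_name_raw=st.sampled_from(
            ["Quercus robur", "Salix alba", "Pinus nigra", "Quercus sp.", "Fagus sylvatica"]
        ),
        source=st.sampled_from(["HOSTS", "DHJ", "JH"]),
        setting=st.sampled_from([WILD, CAPTIVE]),
        questionable=st.booleans(),
    ),
    max_size=40,
)


@given(records_strategy)
@settings(max_examples=60, deadline=None)
def test_partition_conserves_and_dedupe_idempotent(records):
    t = RecordTable(records=records, provenance=[SourceTag(s) for s in ("HOSTS", "DHJ", "JH")])
    wild, captive = partition_by_setting(t)
    assert len(wild) + len(captive) == len(t)
    assert {id(r) for r in wild.records}.isdisjoint({id(r) for r in captive.records})
    d1 = dedupe_records(t)
    d2 = dedupe_records(d1)
    assert [r.key() for r in d1.records] == [r.key() for r in d2.records]
    assert {r.key() for r in d1.records} == {r.key() for r in t.records}


def test_roundtrip_write_read(tmp_path, table, rec, lookup, checklist):
    t = table(
        [rec("Actias luna", "Quercus robur"), rec("Actias luna", "Quercus sp."),
         rec("Manduca sexta", "Xyzus blah", source="JH", setting=CAPTIVE)],
        ["HOSTS", "JH"],
    )
    resolved, _, _ = resolve_records(t, lookup, checklist)
    p = tmp_path / "out.csv"
    resolved.write_csv(p)
    back = read_record_table(
        p, mapping={"plant_name": "plant_name_raw"}
    )
    assert len(back) == len(resolved)
    for a, b in zip(resolved.records, back.records):
        assert a.moth_species == b.moth_species
        assert a.plant_name_raw == b.plant_name_raw
        assert a.source == b.source
        assert a.setting == b.setting
        assert a.plant == b.plant
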