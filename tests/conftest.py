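import pytest

from polyphagy import (
    WILD,
    FoodPlantRecord,
    MothChecklistEntry,
    PlantLookup,
    RecordTable,
    SourceTag,
    parse_newick,
    resolve_plant,
)


@pytest.fixture
def lookup():
    """Small plant taxonomy: two angiosperm families, one gymnosperm."""
    return PlantLookup(
        genus_to_family={
            "Quercus": "Fagaceae",
            "Fagus": "Fagaceae",
            "Salix": "Salicaceae",
            "Populus": "Salicaceae",
            "Pinus": "Pinaceae",
            "Abies": "Pinaceae",
        },
        family_to_order={
            "Fagaceae": "Fagales",
            "Salicaceae": "Malpighiales",
            "Pinaceae": "Pinales",
        },
        family_to_group={
            "Fagaceae": "angiosperm",
            "Salicaceae": "angiosperm",
            "Pinaceae": "gymnosperm",
        },
        synonyms={"Qercus": "Quercus", "Salix weirdii": "Salix alba"},
    )


@pytest.fixture
def checklist():
    return {
        "Actias": MothChecklistEntry("Saturniidae", "Saturniinae", "Saturniini", "Actias", 30),
        "Manduca": MothChecklistEntry("Sphingidae", "Sphinginae", "Sphingini", "Manduca", 70),
    }


@pytest.fixture
def demo_tree():
    """The worked four-tip tree: ((A:1,B:2):3,(C:4,D:5):6); total length 21."""
    return parse_newick("((A:1,B:2):3,(C:4,D:5):6);")


@pytest.fixture
def family_tree():
    """Tiny dated tree whose tips are plant family names."""
    return parse_newick("((Fagaceae:40,Salicaceae:40):60,Rosaceae:100);")


@pytest.fixture
def rec(lookup):
    """Factory for resolved records against the small lookup."""

    def make(
        moth: str,
        plant_raw: str,
        source: str = "HOSTS",
        setting: str = WILD,
        questionable: bool = False,
        resolve: bool = True,
    ) -> FoodPlantRecord:
        r = FoodPlantRecord(
            moth_species=moth,
            plant_name_raw=plant_raw,
            source=source,
            setting=setting,
            questionable=questionable,
        )
        if resolve:
            r.plant = resolve_plant(plant_raw, lookup)
        return r

    return make


@pytest.fixture
def table(rec):
    def make(records, sources=("HOSTS",)):
        return RecordTable(records=list(records), provenance=[SourceTag(s) for s in sources])

    return make
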