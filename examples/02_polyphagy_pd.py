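"""Score polyphagy as Faith's phylogenetic diversity of the plant families
a caterpillar eats.

Uses a small dated tree over four plant families. A species eating two
distantly related families gets a higher score than one eating two close
relatives, even though both eat "two families"; gymnosperm records are
excluded before scoring.
"""

from polyphagy import (
    PlantLookup,
    faith_pd,
    genus_pd_score,
    parse_newick,
)
from polyphagy.phylodiversity import PDResult, pd_from_families

# dated tree, branch lengths in Myr: rosids (Fagaceae+Salicaceae) vs asterids
tree = parse_newick("((Fagaceae:60,Salicaceae:60):40,(Solanaceae:80,Rubiaceae:80):20);")

lookup = PlantLookup(
    genus_to_family={"Quercus": "Fagaceae", "Salix": "Salicaceae",
                     "Solanum": "Solanaceae", "Coffea": "Rubiaceae",
                     "Pinus": "Pinaceae"},
    family_to_order={"Fagaceae": "Fagales", "Salicaceae": "Malpighiales",
                     "Solanaceae": "Solanales", "Rubiaceae": "Gentianales",
                     "Pinaceae": "Pinales"},
    family_to_group={"Fagaceae": "angiosperm", "Salicaceae": "angiosperm",
                     "Solanaceae": "angiosperm", "Rubiaceae": "angiosperm",
                     "Pinaceae": "gymnosperm"},
)

close = {"Fagaceae", "Salicaceae"}          # two related families
far = {"Fagaceae", "Solanaceae"}            # two distant families
print("PD, root included (default): close pair", faith_pd(tree, close), "Myr;",
      "distant pair", faith_pd(tree, far), "Myr")
print("PD, root excluded:           close pair", faith_pd(tree, close, False), "Myr;",
      "distant pair", faith_pd(tree, far, False), "Myr")

# gymnosperm families are dropped before scoring; a gymnosperm-only feeder
# has no defined score
pd_val, used, missing = pd_from_families({"Fagaceae", "Pinaceae"}, tree, lookup)
print("mixed feeder: families scored =", sorted(used), "-> PD =", pd_val)
pd_val, used, _ = pd_from_families({"Pinaceae"}, tree, lookup)
print("gymnosperm-only feeder: PD =", pd_val, "(undefined)")

# a genus score is the mean over its species' defined scores
species = [
    PDResult("Mystax unus", close, set(), faith_pd(tree, close)),
    PDResult("Mystax duo", far, set(), faith_pd(tree, far)),
    PDResult("Mystax tres", set(), set(), None),  # gymnosperm-only
]
print("genus PD score (mean of defined species scores):", genus_pd_score(species), "Myr")
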