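"""Name normalization and resolution against local plant and moth lookup tables.

Food-plant compilations mix verbatim strings from many sources: author
citations ("Quercus robur L."), open nomenclature qualifiers ("Quercus sp.",
"Prunus cf. avium"), hybrid markers and subspecific epithets. This module
reduces every name to a canonical binomial (or genus), then resolves plants
to a genus/family/order lineage with an angiosperm/gymnosperm flag, and
moths to their family/subfamily/tribe via a checklist. Resolution is purely
local-table driven so a run is reproducible without network access; the
packaged lookup format mirrors what one would export from a nomenclator
such as IPNI.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

ANGIOSPERM = "angiosperm"
GYMNOSPERM = "gymnosperm"

#: open-nomenclature markers meaning "identified to genus only"
_GENUS_ONLY_QUALIFIERS = {"sp", "spp", "sp?", "indet", "gen", "genus"}
#: qualifiers that precede a tentative epithet which we keep
_COMPARE_QUALIFIERS = {"cf", "aff", "nr"}
#: infraspecific rank markers: everything from here on is truncated
_INFRA_QUALIFIERS = {"var", "subsp", "ssp", "f", "forma", "subvar", "cv"}

_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class NormalizedName:
    """Canonical form of a taxon name string.

    ``name`` is "" when the input is unresolvable (empty after cleaning);
    ``genus_only`` marks names without a species epithet; ``had_qualifier``
    records whether an open-nomenclature qualifier was stripped.
    """

    name: str
    genus_only: bool = False
    had_qualifier: bool = False

    def __bool__(self) -> bool:  # unresolvable marker is falsy
        return bool(self.name)

    @property
    def genus(self) -> str:
        return self.name.split(" ", 1)[0] if self.name else ""


@dataclass(frozen=True)
class PlantLineage:
    """Resolved plant classification at genus rank or below."""

    genus: str
    species: str | None
    family: str
    order: str
    group: str  # ANGIOSPERM or GYMNOSPERM

    @property
    def is_angiosperm(self) -> bool:
        return self.group == ANGIOSPERM


@dataclass(frozen=True)
class MothChecklistEntry:
    family: str
    subfamily: str
    tribe: str
    genus: str
    total_species: int


def _clean_token(tok: str) -> str:
    return tok.strip(".,;:()[]\"'")


def normalize_name(raw: str) -> NormalizedName:
    """Reduce a verbatim taxon name to ``Genus`` or ``Genus epithet``.

    Rules: trim and collapse whitespace; strip hybrid markers; capitalize
    the genus and lower-case the epithet; drop author citations (any token
    after the epithet, or a capitalized/parenthesised second token) and
    open-nomenclature qualifiers, truncating infraspecific names to the
    binomial. Qualifier presence is reported on the returned value.
    """
    s = raw.replace("\xa0", " ").replace("×", " ").strip()
    s = _WS_RE.sub(" ", s)
    tokens = [t for t in s.split(" ") if t]
    # leading hybrid marker written as a plain letter x
    while tokens and tokens[0].lower() in {"x", "×"}:
        tokens = tokens[1:]
    if not tokens:
        return NormalizedName("")
    genus = _clean_token(tokens[0])
    if not genus or not genus[0].isalpha():
        return NormalizedName("")
    genus = genus.capitalize()

    epithet: str | None = None
    had_qualifier = False
    if len(tokens) > 1:
        second = _clean_token(tokens[1])
        key = second.lower().rstrip("?")
        if key in _GENUS_ONLY_QUALIFIERS:
            had_qualifier = True
        elif key in _COMPARE_QUALIFIERS:
            had_qualifier = True
            if len(tokens) > 2:
                cand = _clean_token(tokens[2])
                if cand and cand[0].islower():
                    epithet = cand.lower()
        elif key in _INFRA_QUALIFIERS:
            had_qualifier = True
        elif second and len(second) >= 3 and second.isupper() and second.isalpha():
            # an all-caps word is a shouted epithet, not an author abbreviation
            epithet = second.lower()
        elif second and (second[0].isupper() or tokens[1].startswith("(")):
            # author citation directly after the genus
            epithet = None
        elif second and second[0].isalpha():
            epithet = second.lower()
    if epithet in (None, ""):
        return NormalizedName(genus, genus_only=True, had_qualifier=had_qualifier)
    return NormalizedName(f"{genus} {epithet}", genus_only=False, had_qualifier=had_qualifier)


@dataclass
class PlantLookup:
    """Local plant taxonomy: genus -> family -> order, family -> group,
    plus a synonym map from raw (normalized) names to accepted names.
    """

    genus_to_family: dict[str, str]
    family_to_order: dict[str, str]
    family_to_group: dict[str, str]
    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for fam in set(self.genus_to_family.values()):
            if fam not in self.family_to_order:
                raise ValueError(f"family {fam!r} missing from family_to_order")
            if fam not in self.family_to_group:
                raise ValueError(f"family {fam!r} missing from family_to_group")
        bad = set(self.family_to_group.values()) - {ANGIOSPERM, GYMNOSPERM}
        if bad:
            raise ValueError(f"unknown plant group labels: {sorted(bad)}")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_table(cls, frame: pd.DataFrame, synonyms: Mapping[str, str] | None = None) -> "PlantLookup":
        """Build from a table with columns genus, family, order, group."""
        required = {"genus", "family", "order", "group"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"plant lookup table missing columns: {sorted(missing)}")
        g2f: dict[str, str] = {}
        f2o: dict[str, str] = {}
        f2g: dict[str, str] = {}
        for row in frame.itertuples(index=False):
            genus = str(row.genus).strip()
            family = str(row.family).strip()
            if genus in g2f and g2f[genus] != family:
                raise ValueError(f"genus {genus!r} mapped to two families")
            g2f[genus] = family
            f2o[family] = str(row.order).strip()
            f2g[family] = str(row.group).strip().lower()
        syn = {}
        if synonyms:
            for raw, accepted in synonyms.items():
                n = normalize_name(str(raw))
                if n:
                    syn[n.name] = str(accepted).strip()
        return cls(g2f, f2o, f2g, syn)

    @classmethod
    def read(cls, path: str | Path, synonyms_path: str | Path | None = None) -> "PlantLookup":
        frame = pd.read_csv(path, dtype=str).fillna("")
        synonyms: dict[str, str] = {}
        if synonyms_path is not None:
            sf = pd.read_csv(synonyms_path, dtype=str).fillna("")
            missing = {"raw_name", "accepted_name"} - set(sf.columns)
            if missing:
                raise ValueError(f"synonyms table missing columns: {sorted(missing)}")
            synonyms = dict(zip(sf["raw_name"], sf["accepted_name"]))
        return cls.from_table(frame, synonyms)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genus": g,
                "family": f,
                "order": self.family_to_order[f],
                "group": self.family_to_group[f],
            }
            for g, f in sorted(self.genus_to_family.items())
        ]
        return pd.DataFrame(rows, columns=["genus", "family", "order", "group"])

    def synonyms_frame(self) -> pd.DataFrame:
        rows = [{"raw_name": k, "accepted_name": v} for k, v in sorted(self.synonyms.items())]
        return pd.DataFrame(rows, columns=["raw_name", "accepted_name"])


def resolve_plant(raw: str, lookup: PlantLookup) -> PlantLineage | None:
    """Resolve a verbatim plant name to its lineage, or None if the genus
    is unknown to the lookup (unresolved is a value, not an error).

    Synonym mapping is applied to the normalized name before rank lookup;
    a genus-level synonym rewrites only the genus token.
    """
    norm = normalize_name(raw)
    if not norm:
        return None
    name = norm.name
    if name in lookup.synonyms:
        norm = normalize_name(lookup.synonyms[name])
        if not norm:
            return None
        name = norm.name
    elif norm.genus in lookup.synonyms:
        accepted_genus = normalize_name(lookup.synonyms[norm.genus]).genus
        rest = name.split(" ", 1)
        name = accepted_genus if len(rest) == 1 else f"{accepted_genus} {rest[1]}"
        norm = NormalizedName(name, genus_only=norm.genus_only, had_qualifier=norm.had_qualifier)
    genus = norm.genus
    family = lookup.genus_to_family.get(genus)
    if family is None:
        return None
    species = None if norm.genus_only else norm.name
    return PlantLineage(
        genus=genus,
        species=species,
        family=family,
        order=lookup.family_to_order[family],
        group=lookup.family_to_group[family],
    )


# -- moth checklist --------------------------------------------------------

def read_checklist(path: str | Path) -> dict[str, MothChecklistEntry]:
    """Read a moth checklist CSV (family,subfamily,tribe,genus,total_species)
    into a genus-keyed dict."""
    frame = pd.read_csv(path, dtype=str).fillna("")
    required = {"family", "subfamily", "tribe", "genus", "total_species"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"checklist missing columns: {sorted(missing)}")
    out: dict[str, MothChecklistEntry] = {}
    for row in frame.itertuples(index=False):
        genus = str(row.genus).strip()
        out[genus] = MothChecklistEntry(
            family=str(row.family).strip(),
            subfamily=str(row.subfamily).strip(),
            tribe=str(row.tribe).strip(),
            genus=genus,
            total_species=int(float(row.total_species)) if str(row.total_species).strip() else 0,
        )
    return out


def checklist_frame(checklist: Mapping[str, MothChecklistEntry]) -> pd.DataFrame:
    rows = [
        {
            "family": e.family,
            "subfamily": e.subfamily,
            "tribe": e.tribe,
            "genus": e.genus,
            "total_species": e.total_species,
        }
        for e in sorted(checklist.values(), key=lambda e: (e.family, e.genus))
    ]
    return pd.DataFrame(rows, columns=["family", "subfamily", "tribe", "genus", "total_species"])


def resolve_moth(
    raw: str, checklist: Mapping[str, MothChecklistEntry]
) -> tuple[str, str, str, str, str]:
    """Resolve a moth name: (family, subfamily, tribe, genus, species).

    The genus is the first token of the normalized binomial; higher ranks
    come from the checklist. A genus absent from the checklist yields empty
    higher ranks (the record is retained and flagged by the caller).
    """
    norm = normalize_name(raw)
    if not norm:
        return ("", "", "", "", "")
    entry = checklist.get(norm.genus)
    if entry is None:
        return ("", "", "", norm.genus, norm.name)
    return (entry.family, entry.subfamily, entry.tribe, norm.genus, norm.name)


def exclude_gymnosperm_families(families: Iterable[str], lookup: PlantLookup) -> set[str]:
    """Return the angiosperm subset of a family set.

    Phylogenetic-diversity polyphagy scores are computed on angiosperms
    only: the deep split between angiosperms and gymnosperms would otherwise
    dominate the branch-length sum. Families unknown to the lookup pass
    through with a warning.
    """
    out: set[str] = set()
    for fam in families:
        group = lookup.family_to_group.get(fam)
        if group is None:
            logger.warning("family %r unknown to plant lookup; passing through", fam)
            out.add(fam)
        elif group == ANGIOSPERM:
            out.add(fam)
    return out
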