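"""Faith's phylogenetic diversity on a dated plant-family tree, used as a
polyphagy score.

The polyphagy score of a moth species is the PD of the set of angiosperm
plant families its caterpillars eat in the wild: the summed branch lengths
of the minimal subtree connecting those families' tips on a dated
family-level phylogeny. With the root included (the default, matching the
common convention of community-phylogenetics software), a species feeding
on a single family scores the root-to-tip path length rather than zero.
Genus scores are the arithmetic mean of the defined species scores.

Gymnosperm families are excluded before scoring: the deep branch separating
gymnosperms from angiosperms would otherwise swamp the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .taxonomy import PlantLookup, exclude_gymnosperm_families

logger = logging.getLogger(__name__)


@dataclass
class PDResult:
    """Per-moth-species PD outcome with provenance of the tip set used."""

    moth_species: str
    families_used: set[str]
    families_missing_from_tree: set[str]
    pd: float | None


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single rooted Newick tree with branch lengths.

    Raises ValueError on malformed input (message carries the parser's
    position information) or duplicate tip labels.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels in tree: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"branch without length above node {edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
            )
        if edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def read_tree(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def tip_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon is not None}


def total_branch_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths, excluding any length on the root edge."""
    total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.length is None:
            continue
        total += edge.length
    return total


def faith_pd(tree: dendropy.Tree, tips: Iterable[str], include_root: bool = True) -> float:
    """Faith's PD of a tip subset.

    include_root=True sums branch lengths over the union of root-to-tip
    paths of the named tips; include_root=False restricts the sum to edges
    below the most recent common ancestor of the set (a single tip then
    scores 0). One postorder pass marks, for every edge, how many of the
    selected tips lie below it: an edge contributes when at least one
    selected tip is below it and — for the rootless convention — at least
    one is not.
    """
    wanted = set(tips)
    if not wanted:
        raise ValueError("faith_pd requires a non-empty tip set")
    labels = tip_labels(tree)
    unknown = wanted - labels
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)}")

    m = len(wanted)
    counts: dict[int, int] = {}
    total = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = 1 if (node.taxon is not None and node.taxon.label in wanted) else 0
        else:
            k = sum(counts[id(ch)] for ch in node.child_nodes())
        counts[id(node)] = k
        if node is tree.seed_node or node.edge.length is None:
            continue
        if k > 0 and (include_root or k < m):
            total += node.edge.length
    return total


def collapse_to_families(
    tree: dendropy.Tree, tip_to_family: Mapping[str, str]
) -> dendropy.Tree:
    """Reduce a species-level tree to family rank.

    Keeps one exemplar tip per family — the lexicographically first tip
    label mapped to that family — prunes the rest, and relabels the kept
    tip with the family name. Tips absent from the mapping are pruned.
    """
    exemplar: dict[str, str] = {}
    for label in sorted(tip_labels(tree)):
        fam = tip_to_family.get(label)
        if fam is not None and fam not in exemplar:
            exemplar[fam] = label
    if not exemplar:
        raise ValueError("no tree tips map to any family")
    keep = set(exemplar.values())
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    label_to_family = {v: k for k, v in exemplar.items()}
    for leaf in pruned.leaf_node_iter():
        if leaf.taxon is not None:
            leaf.taxon.label = label_to_family[leaf.taxon.label]
    return pruned


def pd_from_families(
    families: Iterable[str],
    tree: dendropy.Tree,
    lookup: PlantLookup,
    include_root: bool = True,
) -> tuple[float | None, set[str], set[str]]:
    """PD over a wild plant-family set: exclude gymnosperms, drop families
    absent from the tree (with a warning), return (pd, used, missing).
    pd is None when no usable family remains."""
    angiosperm = exclude_gymnosperm_families(set(families), lookup)
    labels = tip_labels(tree)
    used = angiosperm & labels
    missing = angiosperm - labels
    if missing:
        logger.warning("families missing from tree, dropped from PD: %s", sorted(missing))
    if not used:
        return None, used, missing
    return faith_pd(tree, used, include_root=include_root), used, missing


def species_pd(
    summary,
    tree: dendropy.Tree,
    lookup: PlantLookup,
    include_root: bool = True,
) -> PDResult:
    """Polyphagy PD of one moth species from its wild plant-family list."""
    families = set(summary.wild.families)
    pd, used, missing = pd_from_families(families, tree, lookup, include_root=include_root)
    return PDResult(
        moth_species=summary.moth_species,
        families_used=used,
        families_missing_from_tree=missing,
        pd=pd,
    )


def genus_pd_score(species_results: Sequence[PDResult]) -> float | None:
    """Mean of the defined species PD scores within a genus; None when no
    species has a defined score (e.g. gymnosperm-only feeders)."""
    if not species_results:
        raise ValueError("genus_pd_score requires at least one species result")
    defined = [r.pd for r in species_results if r.pd is not None]
    if not defined:
        return None
    return float(sum(defined)) / len(defined)
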