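"""Shared vs. lineage-specific WGD classification from rooted gene trees.

For a WGD-derived paralog pair in a focal species, the gene tree of the
pair plus homologs from a partner lineage and an outgroup distinguishes
two histories.  If the duplication predates the focal/partner speciation
(a shared WGD), each paralog clusters with its own partner-species
ortholog: ``((F1,P1),(F2,P2)),O``.  If the focal lineage duplicated
independently after the split, the two paralogs are each other's closest
relatives: ``(((F1,F2),P),O)``.  Classification is purely topological —
branch lengths and tip order are ignored — and trees failing the
preconditions (not exactly two focal tips, missing partner/outgroup,
non-monophyletic outgroup, ambiguous polytomy) are called "other".

Species are parsed from tip labels as the prefix before a configurable
delimiter (default ``_``), e.g. ``Cs_gene0001`` -> species ``Cs``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable

import dendropy


def species_from_label(label: str, delimiter: str = "_") -> str:
    return label.split(delimiter)[0]


@dataclass
class GeneTree:
    """A gene tree with species readable from its tip labels."""

    tree: dendropy.Tree
    tree_id: str = ""
    species_extractor: Callable[[str], str] = species_from_label

    def __post_init__(self) -> None:
        leaves = list(self.tree.leaf_node_iter())
        if len(leaves) < 3:
            raise ValueError(f"tree {self.tree_id}: fewer than 3 tips")
        for leaf in leaves:
            if not self.species_extractor(leaf.taxon.label):
                raise ValueError(
                    f"tree {self.tree_id}: empty species for tip {leaf.taxon.label!r}"
                )

    def tip_labels(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    def species_of(self, label: str) -> str:
        return self.species_extractor(label)


class OutgroupError(ValueError):
    """Outgroup tips missing or not placeable as a clade."""


@dataclass(frozen=True)
class TopologyCall:
    tree_id: str
    call: str  # "shared" | "independent" | "other"
    focal_paralogs: tuple[str, str] | None = None
    reason: str = ""


@dataclass(frozen=True)
class TopologySummary:
    n_shared: int
    n_independent: int
    n_other: int

    @property
    def n_total(self) -> int:
        return self.n_shared + self.n_independent + self.n_other

    @property
    def pct_shared_of_total(self) -> float:
        return 100.0 * self.n_shared / self.n_total if self.n_total else 0.0

    @property
    def pct_independent_of_total(self) -> float:
        return 100.0 * self.n_independent / self.n_total if self.n_total else 0.0

    @property
    def shared_ratio(self) -> float:
        """shared / (shared + independent), in percent; 0 when undefined."""
        decisive = self.n_shared + self.n_independent
        return 100.0 * self.n_shared / decisive if decisive else 0.0


def root_with_outgroup(
    gene_tree: GeneTree, outgroup_species: set[str] | Iterable[str]
) -> GeneTree:
    """Root (a copy of) the tree on the edge separating outgroup from ingroup.

    Raises :class:`OutgroupError` when no outgroup tip is present or the
    outgroup tips cannot form a clade under any rooting.
    """
    outgroup_species = set(outgroup_species)
    tree = gene_tree.tree.clone(depth=1)
    leaves = list(tree.leaf_node_iter())
    out_leaves = [
        l for l in leaves
        if gene_tree.species_of(l.taxon.label) in outgroup_species
    ]
    in_leaves = [l for l in leaves if l not in out_leaves]
    if not out_leaves:
        raise OutgroupError(f"tree {gene_tree.tree_id}: no outgroup tip")
    if not in_leaves:
        raise OutgroupError(f"tree {gene_tree.tree_id}: no ingroup tip")

    # Reroot at an ingroup leaf first so the outgroup MRCA is well defined,
    # then put the root on the edge above the outgroup clade.
    tree.reroot_at_edge(in_leaves[0].edge, update_bipartitions=False)
    out_labels = {l.taxon.label for l in out_leaves}
    if len(out_leaves) == 1:
        target = out_leaves[0]
    else:
        target = tree.mrca(taxa=[l.taxon for l in out_leaves])
        if target is tree.seed_node:
            raise OutgroupError(
                f"tree {gene_tree.tree_id}: outgroup not monophyletic"
            )
        under = {l.taxon.label for l in target.leaf_iter()}
        if under != out_labels:
            raise OutgroupError(
                f"tree {gene_tree.tree_id}: outgroup not monophyletic"
            )
    tree.reroot_at_edge(target.edge, update_bipartitions=False)
    return GeneTree(
        tree=tree,
        tree_id=gene_tree.tree_id,
        species_extractor=gene_tree.species_extractor,
    )


def classify_wgd_topology(
    gene_tree: GeneTree,
    focal_species: str,
    partner_species: set[str] | Iterable[str],
    outgroup_species: set[str] | Iterable[str],
) -> TopologyCall:
    """Call a tree "shared", "independent" or "other" for the focal WGD.

    The tree must contain exactly two focal tips (the paralog pair), at
    least one partner tip and at least one outgroup tip.  After outgroup
    rooting, let M be the MRCA of the two focal tips: the call is
    "independent" when M's subtree holds only focal-species tips, "shared"
    when every child subtree of M holding a focal tip also holds a partner
    tip (the duplication precedes the focal-partner speciation), and
    "other" in all remaining or ambiguous configurations.
    """
    partner_species = set(partner_species)
    outgroup_species = set(outgroup_species)
    sp = gene_tree.species_of
    focal_tips = [t for t in gene_tree.tip_labels() if sp(t) == focal_species]
    if len(focal_tips) != 2:
        return TopologyCall(
            gene_tree.tree_id, "other",
            reason=f"expected 2 focal tips, found {len(focal_tips)}",
        )
    if not any(sp(t) in partner_species for t in gene_tree.tip_labels()):
        return TopologyCall(gene_tree.tree_id, "other", reason="no partner tip")
    try:
        rooted = root_with_outgroup(gene_tree, outgroup_species)
    except OutgroupError as exc:
        return TopologyCall(gene_tree.tree_id, "other", reason=str(exc))

    tree = rooted.tree
    taxa = [
        l.taxon for l in tree.leaf_node_iter()
        if sp(l.taxon.label) == focal_species
    ]
    mrca = tree.mrca(taxa=taxa)
    focal_pair = tuple(sorted(focal_tips))

    species_under = Counter(sp(l.taxon.label) for l in mrca.leaf_iter())
    if set(species_under) == {focal_species}:
        return TopologyCall(
            rooted.tree_id, "independent", focal_paralogs=focal_pair,
            reason="paralogs form a focal-only clade",
        )

    children = mrca.child_nodes()
    focal_children = []
    for child in children:
        under = [sp(l.taxon.label) for l in child.leaf_iter()]
        if focal_species in under:
            focal_children.append((child, under))
    if len(focal_children) != 2:
        return TopologyCall(
            rooted.tree_id, "other", focal_paralogs=focal_pair,
            reason="ambiguous polytomy at the duplication node",
        )
    if all(
        any(s in partner_species for s in under) for _, under in focal_children
    ):
        return TopologyCall(
            rooted.tree_id, "shared", focal_paralogs=focal_pair,
            reason="each paralog clusters with a partner-species ortholog",
        )
    return TopologyCall(
        rooted.tree_id, "other", focal_paralogs=focal_pair,
        reason="partner tips on one side of the duplication node only",
    )


def summarize_calls(calls: Iterable[TopologyCall]) -> TopologySummary:
    counts = Counter(c.call for c in calls)
    return TopologySummary(
        n_shared=counts.get("shared", 0),
        n_independent=counts.get("independent", 0),
        n_other=counts.get("other", 0),
    )


def summary_from_counts(
    n_shared: int, n_independent: int, n_total: int
) -> TopologySummary:
    """Build a summary from published-style counts (total includes 'other')."""
    n_other = n_total - n_shared - n_independent
    if n_other < 0:
        raise ValueError("total smaller than shared + independent")
    return TopologySummary(
        n_shared=n_shared, n_independent=n_independent, n_other=n_other
    )
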