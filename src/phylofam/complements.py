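"""Ancestral gene complements: copy numbers at every species-tree node,
orthogroup delineation by duplication-node cutting, presence/absence
matrices, and per-node duplication bursts.

Copy-number convention (the only one consistent with observed leaf counts):
``N(s)`` counts gene lineages present at species node ``s`` *after* applying
duplications mapped at ``s`` and losses on the edge into ``s``; the family
origin gets ``1 + duplications mapped at the origin``. Along every species
edge ``N(child) - N(parent) = duplications_at(child) - losses(edge)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .reconcile import Reconciliation
from .treeio import Node, SpeciesTree

__all__ = [
    "OrthogroupAssignment",
    "copy_numbers",
    "origin_node",
    "orthogroups",
    "presence_matrix",
    "duplication_bursts",
    "aggregate_groups",
]


def copy_numbers(recon: Reconciliation) -> pd.Series:
    """Lineage count at every species-tree node for one family.

    Indexed by species node label in preorder; zero outside the family's
    origin subtree.
    """
    st = recon.species_tree
    dups = recon.duplications_by_species()
    losses = recon.losses_by_species_edge
    origin = recon.origin()
    counts: dict[str, int] = {label: 0 for label in st.node_labels()}
    counts[origin.label] = 1 + dups.get(origin.label, 0)
    for node in origin.preorder():
        for child in node.children:
            counts[child.label] = (
                counts[node.label]
                - losses.get(child.label, 0)
                + dups.get(child.label, 0)
            )
    return pd.Series(counts, name="copies").reindex(st.node_labels())


def origin_node(recon: Reconciliation) -> str:
    """Species node where the family first appears (mapping of the gene
    root). Raises on an empty family."""
    if recon.gene_tree is None:
        raise ValueError("extinct family has no origin")
    return recon.origin().label


@dataclass
class OrthogroupAssignment:
    """Partition of a family's leaves into orthogroups (speciation-only
    subtrees obtained by cutting at duplication nodes)."""

    family: str
    assignment: dict[str, str]  # leaf label -> orthogroup name
    leaf_species: dict[str, str]  # leaf label -> species label

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for leaf, name in self.assignment.items():
            out.setdefault(name, []).append(leaf)
        return out


def orthogroups(
    recon: Reconciliation,
    leaf_map: dict[str, str],
    reference_species: list[str],
    cut_above: str | None = None,
    separator: str = "_",
    position: str = "prefix",
    family: str = "family",
) -> OrthogroupAssignment:
    """Cut the gene tree at duplication nodes and name the resulting
    orthogroups after the reference-species genes they contain.

    With ``cut_above`` set to a species node label, only duplications mapped
    at that node or above it split groups (deep paralogy only). Orthogroups
    containing no reference-species gene are named ``unnamed-<k>`` in
    deterministic traversal order.
    """
    st = recon.species_tree
    cut_node = st.node(cut_above) if cut_above is not None else None

    def cuts(node: Node) -> bool:
        if recon.events.get(node) != "D":
            return False
        if cut_node is None:
            return True
        return st.is_ancestor_or_equal(recon.mapping[node], cut_node)

    groups: list[list[str]] = []

    def collect(node: Node, bucket: list[str] | None) -> None:
        if node.is_leaf:
            if bucket is None:
                bucket = []
                groups.append(bucket)
            bucket.append(node.label)
            return
        if cuts(node):
            for child in node.children:
                collect(child, None)
            return
        if bucket is None:
            bucket = []
            groups.append(bucket)
        for child in node.children:
            collect(child, bucket)

    collect(recon.gene_tree.root, None)

    def gene_token(leaf: str) -> str:
        if separator not in leaf:
            return leaf
        if position == "prefix":
            return leaf.split(separator, 1)[1]
        return leaf.rsplit(separator, 1)[0]

    ref = set(reference_species)
    assignment: dict[str, str] = {}
    unnamed = 0
    used: dict[str, int] = {}
    for members in groups:
        tokens = sorted(
            {gene_token(l) for l in members if leaf_map[l] in ref}
        )
        if tokens:
            name = "/".join(tokens)
        else:
            unnamed += 1
            name = f"unnamed-{unnamed}"
        if name in used:  # two groups sharing reference names stay distinct
            used[name] += 1
            name = f"{name}.{used[name]}"
        else:
            used[name] = 1
        for leaf in members:
            assignment[leaf] = name
    return OrthogroupAssignment(
        family=family,
        assignment=assignment,
        leaf_species={l: leaf_map[l] for l in assignment},
    )


def presence_matrix(
    assignments: list[OrthogroupAssignment], species: list[str]
) -> pd.DataFrame:
    """Species x orthogroup boolean matrix: present iff the species has at
    least one gene in the orthogroup."""
    columns: dict[str, set[str]] = {}
    for asg in assignments:
        for leaf, name in asg.assignment.items():
            columns.setdefault(name, set()).add(asg.leaf_species[leaf])
    frame = pd.DataFrame(
        {
            name: [sp in present for sp in species]
            for name, present in sorted(columns.items())
        },
        index=pd.Index(species, name="species"),
    )
    return frame


def duplication_bursts(
    recons: list[Reconciliation], species_tree: SpeciesTree
) -> pd.DataFrame:
    """Per species node: duplications mapped there summed across families,
    paired with the summed complement change ``N(node) - N(parent)``."""
    labels = species_tree.node_labels()
    dup_totals = {label: 0 for label in labels}
    delta = {label: 0 for label in labels}
    for recon in recons:
        for label, n in recon.duplications_by_species().items():
            dup_totals[label] += n
        series = copy_numbers(recon)
        for node in species_tree.tree.preorder():
            if node.parent is None:
                delta[node.label] += int(series[node.label])
            else:
                delta[node.label] += int(
                    series[node.label] - series[node.parent.label]
                )
    return pd.DataFrame(
        {"duplications": dup_totals, "delta_copies": delta}
    ).reindex(labels)


def aggregate_groups(
    columns: dict[str, pd.Series], group_map: dict[str, str]
) -> pd.DataFrame:
    """Sum per-family complement columns into per-group columns.

    Every family must be assigned to exactly one group.
    """
    missing = sorted(set(columns) - set(group_map))
    if missing:
        raise ValueError(f"families without a group: {', '.join(missing)}")
    grouped: dict[str, pd.Series] = {}
    for family, series in columns.items():
        group = group_map[family]
        grouped[group] = (
            series.copy() if group not in grouped else grouped[group] + series
        )
    return pd.DataFrame(grouped)
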