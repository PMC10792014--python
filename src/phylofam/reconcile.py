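"""Gene-tree / species-tree reconciliation under weighted duplication-loss
parsimony.

The reconciliation maps every gene-tree node to a species-tree node via the
LCA (last-common-ancestor) mapping, labels internal nodes S (speciation) or
D (duplication), and counts losses from species-tree path lengths between
mapped nodes. LCA mapping is the parsimony-optimal duplication-loss
reconciliation; an exhaustive dynamic-programming oracle over all valid
mappings verifies this in the test suite.

Conventions (shared with the complements module):

* a node is D iff it maps to the same species node as at least one child;
* duplications sit *at* species nodes (undated model): a D at species node
  ``s`` with a child mapped at ``u`` costs ``pathlen(s, u)`` losses, an S
  costs ``pathlen(s, u) - 1``;
* each loss is attributed to a concrete species-tree edge (the off-path
  child edge where the lineage disappeared), so ancestral copy numbers
  balance edge by edge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .treeio import Node, SpeciesTree, Tree, write_newick

__all__ = [
    "CostWeights",
    "Reconciliation",
    "RootingResult",
    "resolve_polytomies",
    "lca_map",
    "label_events",
    "assemble_reconciliation",
    "dl_cost",
    "root_by_dl",
    "reconciliation_to_nhx",
]


@dataclass(frozen=True)
class CostWeights:
    """Parsimony weights: ``c_d`` per duplication, ``c_l`` per loss."""

    c_d: float = 1.0
    c_l: float = 1.0

    def __post_init__(self):
        if self.c_d <= 0:
            raise ValueError("duplication cost must be positive")
        if self.c_l < 0:
            raise ValueError("loss cost must be non-negative")


@dataclass
class Reconciliation:
    """A gene tree embedded in a species tree.

    ``mapping`` and ``events`` are keyed by gene-tree :class:`Node` objects
    (identity-hashed). ``losses_by_species_edge`` is keyed by the child
    label of the species edge carrying the loss; ``losses_by_gene_edge``
    records, for each gene-tree child node, the species edges lost along
    the branch above it.
    """

    gene_tree: Tree
    species_tree: SpeciesTree
    mapping: dict[Node, Node]
    events: dict[Node, str]
    losses_by_species_edge: dict[str, int]
    losses_by_gene_edge: dict[Node, list[str]]

    @property
    def duplication_count(self) -> int:
        return sum(1 for e in self.events.values() if e == "D")

    @property
    def loss_count(self) -> int:
        return sum(self.losses_by_species_edge.values())

    def duplications_by_species(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for node, ev in self.events.items():
            if ev == "D":
                label = self.mapping[node].label
                out[label] = out.get(label, 0) + 1
        return out

    def origin(self) -> Node:
        return self.mapping[self.gene_tree.root]

    def cost(self, weights: CostWeights = CostWeights()) -> float:
        return dl_cost(self, weights)

    def to_dict(self) -> dict:
        return {
            "duplications": self.duplication_count,
            "losses": self.loss_count,
            "origin": self.origin().label,
            "duplications_by_species": self.duplications_by_species(),
            "losses_by_species_edge": dict(self.losses_by_species_edge),
        }


def resolve_polytomies(tree: Tree, seed: int = 0) -> Tree:
    """Return a binary copy; multifurcations are resolved uniformly at
    random (seed-reproducible) with zero-length inserted branches.

    An unrooted tree (``rooted=False``) keeps a trifurcating base; every
    other node becomes strictly binary. Already-binary input comes back
    topologically identical.
    """
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for node in list(out.postorder()):
        limit = 3 if (node.parent is None and not out.rooted) else 2
        while len(node.children) > limit:
            children = sorted(
                node.children, key=lambda c: min(l.label for l in c.leaves())
            )
            i, j = sorted(rng.choice(len(children), size=2, replace=False))
            a, b = children[i], children[j]
            a.detach()
            b.detach()
            joint = Node(length=0.0)
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
    return out


def lca_map(
    gene_tree: Tree, species_tree: SpeciesTree, leaf_map: dict[str, str]
) -> dict[Node, Node]:
    """Bottom-up LCA mapping of every gene-tree node to a species node."""
    mapping: dict[Node, Node] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            if node.label not in leaf_map:
                raise KeyError(f"gene leaf {node.label!r} missing from leaf map")
            mapping[node] = species_tree.node(leaf_map[node.label])
        else:
            out = mapping[node.children[0]]
            for child in node.children[1:]:
                out = species_tree.lca(out, mapping[child])
            mapping[node] = out
    return mapping


def _path_down(species_tree: SpeciesTree, anc: Node, desc: Node) -> list[Node]:
    """Species nodes from ``anc`` down to ``desc`` inclusive."""
    chain = [desc]
    while chain[-1] is not anc:
        chain.append(chain[-1].parent)
        if chain[-1] is None:
            raise ValueError("not an ancestor")
    chain.reverse()
    return chain


def assemble_reconciliation(
    gene_tree: Tree,
    species_tree: SpeciesTree,
    mapping: dict[Node, Node],
    events: dict[Node, str],
) -> Reconciliation:
    """Derive per-edge loss placements from a mapping + event labelling."""
    losses_by_species_edge: dict[str, int] = {}
    losses_by_gene_edge: dict[Node, list[str]] = {}
    for gnode in gene_tree.preorder():
        if gnode.is_leaf:
            continue
        s = mapping[gnode]
        for child in gnode.children:
            u = mapping[child]
            path = _path_down(species_tree, s, u)
            # S: lineage forks at s itself, losses start below; D: the extra
            # copy also forks (and can die) at s.
            start = 1 if events[gnode] == "S" else 0
            lost_edges = []
            for k in range(start, len(path) - 1):
                on_path = path[k + 1]
                for sib in path[k].children:
                    if sib is not on_path:
                        lost_edges.append(sib.label)
            losses_by_gene_edge[child] = lost_edges
            for label in lost_edges:
                losses_by_species_edge[label] = (
                    losses_by_species_edge.get(label, 0) + 1
                )
    return Reconciliation(
        gene_tree, species_tree, mapping, events,
        losses_by_species_edge, losses_by_gene_edge,
    )


def label_events(
    gene_tree: Tree, mapping: dict[Node, Node], species_tree: SpeciesTree
) -> Reconciliation:
    """Label each internal gene node S or D and place loss events.

    A node is D iff it maps to the same species node as at least one of its
    children; under LCA mapping this is exactly the set of unavoidable
    duplications.
    """
    events: dict[Node, str] = {}
    for gnode in gene_tree.preorder():
        if gnode.is_leaf:
            continue
        s = mapping[gnode]
        events[gnode] = (
            "D" if any(mapping[c] is s for c in gnode.children) else "S"
        )
        for child in gnode.children:
            if not species_tree.is_ancestor_or_equal(s, mapping[child]):
                raise ValueError("mapping violates ancestry; not a valid embedding")
    return assemble_reconciliation(gene_tree, species_tree, mapping, events)


def reconcile(
    gene_tree: Tree, species_tree: SpeciesTree, leaf_map: dict[str, str]
) -> Reconciliation:
    """LCA-parsimony reconciliation of a rooted binary gene tree."""
    if not gene_tree.rooted:
        raise ValueError("gene tree must be rooted; use root_by_dl first")
    for node in gene_tree.preorder():
        if node.children and len(node.children) != 2:
            raise ValueError(
                "gene tree contains a polytomy; use resolve_polytomies first"
            )
    mapping = lca_map(gene_tree, species_tree, leaf_map)
    return label_events(gene_tree, mapping, species_tree)


def dl_cost(recon: Reconciliation, weights: CostWeights = CostWeights()) -> float:
    return weights.c_d * recon.duplication_count + weights.c_l * recon.loss_count


# ---------------------------------------------------------------------------
# Rooting by duplication-loss parsimony
# ---------------------------------------------------------------------------


@dataclass
class RootingResult:
    tree: Tree
    reconciliation: Reconciliation
    cost: float
    co_optimal_roots: list[tuple[str, ...]] = field(default_factory=list)
    """Each co-optimal root branch, identified by the sorted leaf labels of
    its smaller side (smaller-side key used for tie-breaking)."""


def _unrooted_adjacency(tree: Tree):
    """Adjacency map of the unrooted topology (degree-2 base suppressed)."""
    adj: dict[int, dict[int, float | None]] = {}
    labels: dict[int, str | None] = {}
    counter = itertools.count()
    node_ids: dict[int, int] = {}
    for node in tree.preorder():
        nid = next(counter)
        node_ids[id(node)] = nid
        labels[nid] = node.label if node.is_leaf else None
        adj[nid] = {}
    for node in tree.preorder():
        for child in node.children:
            u, v = node_ids[id(node)], node_ids[id(child)]
            adj[u][v] = child.length
            adj[v][u] = child.length
    for u in list(adj):
        if len(adj[u]) == 2:
            (a, la), (b, lb) = adj[u].items()
            length = None
            if la is not None or lb is not None:
                length = (la or 0.0) + (lb or 0.0)
            del adj[u], adj[a][u], adj[b][u]
            adj[a][b] = length
            adj[b][a] = length
    return adj, labels


def _root_on_edge(adj, labels, u: int, v: int) -> Tree:
    """Build a rooted binary tree with the root splitting edge (u, v)."""

    def build(nid: int, parent: int) -> Node:
        node = Node(labels.get(nid))
        for nbr, length in sorted(adj[nid].items()):
            if nbr == parent:
                continue
            child = build(nbr, nid)
            child.length = length
            node.add_child(child)
        return node

    root = Node()
    left = build(u, v)
    right = build(v, u)
    edge_len = adj[u][v]
    left.length = right.length = None if edge_len is None else edge_len / 2.0
    root.add_child(left)
    root.add_child(right)
    return Tree(root, rooted=True)


def _side_key(side_a: list[str], side_b: list[str]) -> tuple:
    """Deterministic identity/tie-break key for a root branch: the smaller
    side first (by size, then lexicographically)."""
    a, b = sorted(side_a), sorted(side_b)
    if (len(b), b) < (len(a), a):
        a, b = b, a
    return (tuple(a), tuple(b))


def root_by_dl(
    gene_tree: Tree,
    species_tree: SpeciesTree,
    leaf_map: dict[str, str],
    weights: CostWeights = CostWeights(),
) -> RootingResult:
    """Try every branch of the unrooted gene tree as a root position and
    return the rooting of minimal weighted DL cost.

    Ties break deterministically on the smaller-side smallest leaf label
    (then on the full leaf-set key); all co-optimal root branches are
    reported.
    """
    if len(gene_tree.leaves()) < 2:
        raise ValueError("need at least 2 leaves to root")
    adj, labels = _unrooted_adjacency(gene_tree)

    # leaf sets per directed edge, to build tie-break keys cheaply
    def leaves_from(nid: int, parent: int, memo: dict) -> frozenset[str]:
        key = (nid, parent)
        if key not in memo:
            if labels.get(nid) is not None and len(adj[nid]) == 1:
                memo[key] = frozenset([labels[nid]])
            else:
                acc: set[str] = set()
                for nbr in adj[nid]:
                    if nbr != parent:
                        acc |= leaves_from(nbr, nid, memo)
                memo[key] = frozenset(acc)
        return memo[key]

    memo: dict = {}
    best: tuple | None = None
    results: list[tuple[tuple, float, Tree, Reconciliation]] = []
    seen_edges = set()
    for u in sorted(adj):
        for v in sorted(adj[u]):
            if (v, u) in seen_edges:
                continue
            seen_edges.add((u, v))
            rooted = _root_on_edge(adj, labels, u, v)
            recon = reconcile(rooted, species_tree, leaf_map)
            cost = dl_cost(recon, weights)
            key = _side_key(
                sorted(leaves_from(u, v, memo)), sorted(leaves_from(v, u, memo))
            )
            results.append((key, cost, rooted, recon))

    min_cost = min(r[1] for r in results)
    optimal = [r for r in results if r[1] == min_cost]
    optimal.sort(key=lambda r: r[0])
    key, cost, tree, recon = optimal[0]
    return RootingResult(
        tree=tree,
        reconciliation=recon,
        cost=cost,
        co_optimal_roots=[r[0][0] for r in optimal],
    )


# ---------------------------------------------------------------------------
# NHX export
# ---------------------------------------------------------------------------


def reconciliation_to_nhx(recon: Reconciliation) -> str:
    """Serialise the reconciled gene tree with per-node NHX annotations
    (``Sp`` = mapped species, ``Ev`` = S/D on internal nodes); parseable by
    :func:`phylofam.treeio.parse_newick`."""

    def clone(node: Node) -> Node:
        new = Node(node.label, node.length)
        nhx = {"Sp": recon.mapping[node].label}
        if not node.is_leaf:
            nhx["Ev"] = recon.events[node]
        new.nhx = nhx
        for child in node.children:
            new.add_child(clone(child))
        return new

    return write_newick(Tree(clone(recon.gene_tree.root)))
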