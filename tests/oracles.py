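"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the library's own algorithms: dynamic
programming over all valid species mappings for reconciliation, union-find
for components, threshold sweeps for merge points, and set-arithmetic
transfer distances.
"""

from __future__ import annotations

import numpy as np

from phylofam.treeio import Node, SpeciesTree, Tree

INF = float("inf")


# ---------------------------------------------------------------------------
# Exhaustive duplication-loss reconciliation over all event-consistent
# histories (undated model): every gene node may map to any species node
# between the LCA of its leaves and its parent's mapping.
# ---------------------------------------------------------------------------


def dp_min_dl_cost(
    gene_tree: Tree,
    species_tree: SpeciesTree,
    leaf_map: dict[str, str],
    c_d: float = 1.0,
    c_l: float = 1.0,
) -> float:
    """Minimum weighted duplication-loss cost over all valid histories."""

    def candidates(gnode: Node) -> list[Node]:
        lca = species_tree.lca_of(
            [species_tree.node(leaf_map[l.label]) for l in gnode.leaves()]
        )
        return species_tree.ancestors_or_equal(lca)

    memo: dict[tuple[int, int], float] = {}

    def cost(gnode: Node, snode: Node) -> float:
        key = (id(gnode), id(snode))
        if key in memo:
            return memo[key]
        if gnode.is_leaf:
            out = 0.0 if species_tree.node(leaf_map[gnode.label]) is snode else INF
            memo[key] = out
            return out
        left, right = gnode.children
        best = INF
        for s1 in candidates(left):
            if not species_tree.is_ancestor_or_equal(snode, s1):
                continue
            c1 = cost(left, s1)
            if c1 == INF:
                continue
            for s2 in candidates(right):
                if not species_tree.is_ancestor_or_equal(snode, s2):
                    continue
                c2 = cost(right, s2)
                if c2 == INF:
                    continue
                d1 = species_tree.path_length(snode, s1)
                d2 = species_tree.path_length(snode, s2)
                speciation = (
                    s1 is not snode
                    and s2 is not snode
                    and species_tree.lca(s1, s2) is snode
                )
                if speciation:
                    total = c1 + c2 + c_l * (d1 - 1 + d2 - 1)
                else:
                    total = c_d + c1 + c2 + c_l * (d1 + d2)
                best = min(best, total)
        memo[key] = best
        return best

    return min(cost(gene_tree.root, s) for s in candidates(gene_tree.root))


# ---------------------------------------------------------------------------
# Components / merge thresholds
# ---------------------------------------------------------------------------


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


def components_by_union_find(
    vertices: list[str], edges: list[tuple[str, str, float]], threshold: float
) -> list[frozenset[str]]:
    uf = UnionFind(vertices)
    for u, v, p in edges:
        if p <= threshold:
            uf.union(u, v)
    groups: dict[str, set[str]] = {}
    for v in vertices:
        groups.setdefault(uf.find(v), set()).add(v)
    return sorted((frozenset(g) for g in groups.values()), key=sorted)


def merge_threshold_by_sweep(graph, set_a, set_b) -> float | None:
    """Scan the sorted distinct edge P-values, asking components_at-style
    connectivity at each, via an independent union-find."""
    vertices = graph.vertices
    edges = graph.edges()
    for p in sorted({e[2] for e in edges}):
        comps = components_by_union_find(vertices, edges, p)
        for comp in comps:
            if comp & set_a and comp & set_b:
                return p
    return None


# ---------------------------------------------------------------------------
# Transfer distance
# ---------------------------------------------------------------------------


def clades_of(tree: Tree) -> list[frozenset[str]]:
    out = []

    def walk(node: Node) -> frozenset[str]:
        if node.is_leaf:
            s = frozenset([node.label])
        else:
            s = frozenset().union(*(walk(c) for c in node.children))
        if node.parent is not None:
            out.append(s)
        return s

    walk(tree.root)
    return out


def transfer_index_brute(bip: frozenset[str], replicate: Tree) -> int:
    """Min leaves-to-move over every replicate branch, via symmetric set
    differences."""
    leafset = frozenset(replicate.leaf_labels())
    best = len(leafset)
    other = leafset - bip
    for clade in clades_of(replicate):
        best = min(
            best,
            len(bip ^ clade),
            len(other ^ clade),
        )
    return best


# ---------------------------------------------------------------------------
# Random tree generation
# ---------------------------------------------------------------------------


def random_rooted_tree(labels: list[str], rng: np.random.Generator,
                       lengths: bool = False) -> Tree:
    """Uniform-ish random rooted binary tree by sequential leaf attachment."""
    nodes = [Node(label) for label in labels]
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        joint = Node()
        joint.add_child(a)
        joint.add_child(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(joint)
    tree = Tree(nodes[0], rooted=True)
    if lengths:
        for node in tree.preorder():
            if node.parent is not None:
                node.length = float(rng.uniform(0.05, 1.0))
    return tree


def random_species_tree(n_leaves: int, rng: np.random.Generator) -> SpeciesTree:
    labels = [f"S{i}" for i in range(n_leaves)]
    return SpeciesTree(random_rooted_tree(labels, rng))


def random_gene_leaves(
    species: list[str], rng: np.random.Generator, n_leaves: int
) -> list[str]:
    counts: dict[str, int] = {}
    out = []
    for _ in range(n_leaves):
        sp = species[rng.integers(len(species))]
        counts[sp] = counts.get(sp, 0) + 1
        out.append(f"{sp}_{counts[sp]}")
    return out
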