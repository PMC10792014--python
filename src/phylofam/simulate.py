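"""Birth-death gene-family simulation with ground-truth event logs.

Gene lineages evolve along a species tree: on every species-tree edge each
lineage independently waits exponential times and either duplicates (rate
``dup_rate``) or dies (rate ``loss_rate``); at internal species nodes every
surviving lineage speciates into both child edges. Extinct subtrees are
pruned from the emitted gene tree but every event is retained in the
:class:`EventLog`, so the observed tree looks like real data while the log
keeps full truth.

The emitted gene tree carries the true embedding as NHX annotations
(``Sp`` = species placement, ``Ev`` = S/D), from which a ground-truth
reconciliation object can be rebuilt (:func:`true_reconciliation`) and used
as an oracle for the inference modules.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .treeio import Node, SpeciesTree, Tree

__all__ = [
    "SimParams",
    "Event",
    "EventLog",
    "simulate_family",
    "simulate_families",
    "simulate_similarity",
    "perturb_tree",
    "true_reconciliation",
]


@dataclass
class SimParams:
    """Rates are per lineage per unit branch length; ``overrides`` maps a
    species-tree edge (identified by its child node label) to an
    edge-specific ``(dup_rate, loss_rate)`` pair."""

    dup_rate: float = 0.5
    loss_rate: float = 0.2
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        for key, (lam, mu) in self.overrides.items():
            if lam < 0 or mu < 0:
                raise ValueError(f"negative rate override for edge {key!r}")

    def rates_for(self, edge_child_label: str) -> tuple[float, float]:
        return self.overrides.get(edge_child_label, (self.dup_rate, self.loss_rate))


@dataclass
class Event:
    """One logged event.

    ``place`` is a species-tree node label: the node itself for speciations,
    the lower node of the edge for duplications and losses. ``time`` is the
    fractional position along the edge (duplication/loss only).
    ``children`` are the lineage ids created by a speciation/duplication.
    """

    type: str
    place: str
    lineage: int
    time: float | None = None
    children: tuple[int, int] | None = None

    def to_dict(self) -> dict:
        out = {"type": self.type, "place": self.place, "lineage": self.lineage}
        if self.time is not None:
            out["time"] = self.time
        if self.children is not None:
            out["children"] = list(self.children)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        children = tuple(d["children"]) if "children" in d else None
        return cls(d["type"], d["place"], d["lineage"], d.get("time"), children)


class EventLog:
    """Ordered ground-truth record of one family's history."""

    def __init__(self, events: list[Event], root_species: str, extinct: bool):
        self.events = events
        self.root_species = root_species
        self.extinct = extinct

    def duplications(self) -> list[Event]:
        return [e for e in self.events if e.type == "duplication"]

    def losses(self) -> list[Event]:
        return [e for e in self.events if e.type == "loss"]

    def duplications_by_edge(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.duplications():
            out[e.place] = out.get(e.place, 0) + 1
        return out

    def _lineage_children(self) -> dict[int, tuple[int, int]]:
        return {
            e.lineage: e.children
            for e in self.events
            if e.children is not None
        }

    def replay(
        self, species_tree: SpeciesTree, mode: str = "all"
    ) -> dict[str, int]:
        """Propagate logged lineage counts down the species tree.

        Returns the number of lineages present at every species node (the
        count after the events on the node's incoming edge). Modes:

        * ``all`` — every logged lineage, extinct ones included;
        * ``surviving`` — only lineages with at least one extant descendant;
        * ``observable`` — like ``surviving``, but additionally clipping the
          stem above the observed family root (the first branching into two
          surviving lineages): basal one-sided losses are invisible in the
          pruned gene tree, so this is exactly what a reconciliation of the
          observed tree can see.
        """
        if mode not in ("all", "surviving", "observable"):
            raise ValueError(f"unknown replay mode {mode!r}")
        speciations = {
            (e.place, e.lineage): e.children
            for e in self.events
            if e.type == "speciation"
        }
        edge_events: dict[str, list[Event]] = {}
        for e in self.events:
            if e.type in ("duplication", "loss"):
                edge_events.setdefault(e.place, []).append(e)
        for lst in edge_events.values():
            lst.sort(key=lambda e: e.time)

        present: dict[str, set[int]] = {self.root_species: {0}}
        root = species_tree.node(self.root_species)
        for snode in root.preorder():
            if snode.is_leaf:
                continue
            here = present.get(snode.label, set())
            for idx, child in enumerate(snode.children):
                current = {
                    speciations[(snode.label, lin)][idx]
                    for lin in here
                    if (snode.label, lin) in speciations
                }
                for e in edge_events.get(child.label, []):
                    if e.lineage in current:
                        if e.type == "loss":
                            current.discard(e.lineage)
                        else:
                            current.discard(e.lineage)
                            current.update(e.children)
                present[child.label] = current

        if mode == "all":
            counts = {label: len(lins) for label, lins in present.items()}
            for label in species_tree.node_labels():
                counts.setdefault(label, 0)
            return counts

        extant: set[int] = set()
        for leaf_label in species_tree.leaf_labels():
            extant |= present.get(leaf_label, set())
        kids = self._lineage_children()
        memo: dict[int, bool] = {}

        def survives(lin: int) -> bool:
            if lin in memo:
                return memo[lin]
            ok = lin in extant or any(survives(k) for k in kids.get(lin, ()))
            memo[lin] = ok
            return ok

        counts = {
            label: sum(1 for lin in lins if survives(lin))
            for label, lins in present.items()
        }
        for label in species_tree.node_labels():
            counts.setdefault(label, 0)

        if mode == "observable" and not self.extinct:
            # clip the unobservable stem: walk the surviving chain down from
            # the root lineage until it first branches into two surviving
            # children; everything strictly above that placement is invisible
            # in the pruned gene tree.
            branch_events = {
                e.lineage: e for e in self.events if e.children is not None
            }
            lineage = 0
            origin = self.root_species
            while True:
                event = branch_events.get(lineage)
                if event is None:  # extant unduplicated lineage: a species leaf
                    origin = next(
                        label
                        for label in species_tree.leaf_labels()
                        if lineage in present.get(label, set())
                    )
                    break
                alive = [k for k in event.children if survives(k)]
                if len(alive) == 2:
                    origin = event.place
                    break
                lineage = alive[0]
            node = species_tree.node(origin).parent
            while node is not None:
                counts[node.label] = 0
                node = node.parent
        return counts

    def to_dict(self) -> dict:
        return {
            "root_species": self.root_species,
            "extinct": self.extinct,
            "events": [e.to_dict() for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventLog":
        return cls(
            [Event.from_dict(e) for e in d["events"]],
            d["root_species"],
            d["extinct"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------


def simulate_family(
    species_tree: SpeciesTree,
    params: SimParams,
    separator: str = "_",
    family_tag: str = "",
) -> tuple[Tree | None, EventLog]:
    """Simulate one gene family; returns ``(gene_tree, event_log)``.

    The gene tree is ``None`` when the family went extinct (the log still
    records what happened). Gene-tree leaves are named
    ``<species><separator><family_tag><lineage id>``; pass a per-family tag
    to keep ids unique across families. Branch lengths accumulate simulated
    time; internal nodes carry the true species placement and event type in
    their NHX dict.
    """
    for parent, child in species_tree.edges():
        if child.length is None or child.length <= 0:
            raise ValueError(
                f"species-tree edge into {child.label!r} must have a "
                "positive branch length"
            )
    for key in params.overrides:
        species_tree.node(key)  # raises KeyError for unknown edges

    rng = np.random.default_rng(params.seed)
    counter = itertools.count(1)
    events: list[Event] = []

    def at_node(snode: Node, lineage: int) -> Node | None:
        """Lineage has just arrived at species node ``snode``."""
        if snode.is_leaf:
            leaf = Node(f"{snode.label}{separator}{family_tag}{lineage}",
                        length=0.0)
            leaf.nhx = {"Sp": snode.label}
            return leaf
        kids = (next(counter), next(counter))
        events.append(Event("speciation", snode.label, lineage, children=kids))
        results = [
            along_edge(child, kid, 0.0)
            for child, kid in zip(snode.children, kids)
        ]
        alive = [r for r in results if r is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        node = Node(length=0.0)
        node.nhx = {"Sp": snode.label, "Ev": "S"}
        for sub in alive:
            node.add_child(sub)
        return node

    def along_edge(sedge_child: Node, lineage: int, t: float) -> Node | None:
        """Lineage travels down the edge into ``sedge_child`` from time ``t``."""
        lam, mu = params.rates_for(sedge_child.label)
        total = lam + mu
        blen = sedge_child.length
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if t + wait >= blen:
            sub = at_node(sedge_child, lineage)
            if sub is None:
                return None
            sub.length += blen - t
            return sub
        t2 = t + wait
        if rng.random() < lam / total:  # duplication
            kids = (next(counter), next(counter))
            events.append(
                Event("duplication", sedge_child.label, lineage,
                      time=t2 / blen, children=kids)
            )
            left = along_edge(sedge_child, kids[0], t2)
            right = along_edge(sedge_child, kids[1], t2)
            if left is not None and right is not None:
                node = Node(length=wait)
                # undated convention: a duplication on an edge maps to the
                # edge's lower node
                node.nhx = {"Sp": sedge_child.label, "Ev": "D"}
                node.add_child(left)
                node.add_child(right)
                return node
            survivor = left if left is not None else right
            if survivor is not None:
                survivor.length += wait
            return survivor
        events.append(Event("loss", sedge_child.label, lineage, time=t2 / blen))
        return None

    root_result = at_node(species_tree.root, 0)
    log = EventLog(events, species_tree.root.label, extinct=root_result is None)
    if root_result is None:
        return None, log
    root_result.length = None  # no edge above the gene-tree root
    return Tree(root_result, rooted=True), log


def simulate_families(
    species_tree: SpeciesTree,
    n_families: int,
    params: SimParams,
    separator: str = "_",
) -> list[tuple[Tree | None, EventLog]]:
    """Simulate ``n_families`` families with per-family seeds derived from
    ``params.seed`` (byte-reproducible)."""
    out = []
    for k in range(n_families):
        child_seed = int(
            np.random.SeedSequence(entropy=[params.seed, k]).generate_state(1)[0]
        )
        fam_params = SimParams(
            params.dup_rate, params.loss_rate, dict(params.overrides), child_seed
        )
        out.append(
            simulate_family(
                species_tree, fam_params, separator=separator,
                family_tag=f"f{k}g" if n_families > 1 else "",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Ground-truth reconciliation of the observed (pruned) tree
# ---------------------------------------------------------------------------


def true_reconciliation(gene_tree: Tree, species_tree: SpeciesTree):
    """Rebuild the true reconciliation from the simulator's NHX annotations.

    Losses are the *effective* per-species-edge losses visible after pruning
    (each off-path side branch with no surviving descendant counts once),
    which is exactly what ancestral copy-number propagation needs.
    """
    from .reconcile import Reconciliation, assemble_reconciliation

    mapping = {}
    events = {}
    for node in gene_tree.preorder():
        if node.nhx is None or "Sp" not in node.nhx:
            raise ValueError("gene tree lacks simulator truth annotations")
        mapping[node] = species_tree.node(node.nhx["Sp"])
        if not node.is_leaf:
            events[node] = node.nhx["Ev"]
    return assemble_reconciliation(gene_tree, species_tree, mapping, events)


# ---------------------------------------------------------------------------
# Synthetic similarity matrices
# ---------------------------------------------------------------------------


def _patristic_distances(tree: Tree) -> dict[tuple[str, str], float]:
    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        for child in node.children:
            depth[id(child)] = depth[id(node)] + (child.length or 0.0)
    leaves = tree.leaves()
    anc_sets = {}
    for leaf in leaves:
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent
        anc_sets[id(leaf)] = chain
    out = {}
    for i, a in enumerate(leaves):
        aset = {id(x) for x in anc_sets[id(a)]}
        for b in leaves[i + 1:]:
            lca = next(x for x in anc_sets[id(b)] if id(x) in aset)
            d = depth[id(a)] + depth[id(b)] - 2 * depth[id(lca)]
            out[(a.label, b.label)] = d
    return out


def simulate_similarity(
    gene_trees: list[Tree],
    intercept: float = 40.0,
    slope: float = 2.0,
    noise_sd: float = 2.0,
    cross_family_mean: float = 4.0,
    seed: int = 0,
):
    """Emit a :class:`~phylofam.clustering.SimilarityGraph` in which
    within-family similarity decays with patristic distance and
    between-family similarity fluctuates around a low baseline.

    Scores are on the ``-log10 P`` scale (``P = 10**-score``), floored at 0.
    Between-family noise is truncated at two standard deviations: sequences
    without real homology cannot reach arbitrarily high similarity, and an
    unbounded Gaussian tail would let a single spurious strong edge fuse two
    families through transitivity. Vertices are annotated with their
    generative family index (``family`` attribute), the ground truth for
    cluster-recovery tests.
    """
    from .clustering import SimilarityGraph

    if intercept <= cross_family_mean:
        raise ValueError("intercept must exceed cross_family_mean")
    rng = np.random.default_rng(seed)
    graph = SimilarityGraph()
    members: list[list[str]] = []
    for fam_idx, tree in enumerate(gene_trees):
        labels = tree.leaf_labels()
        members.append(labels)
        for label in labels:
            species = label.split("_", 1)[0] if "_" in label else None
            graph.add_vertex(label, family=fam_idx, species=species)
        dists = _patristic_distances(tree)
        for (a, b), d in dists.items():
            score = intercept - slope * d
            if noise_sd > 0:
                score += rng.normal(0.0, noise_sd)
            graph.add_edge(a, b, score=max(score, 0.0))
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            for a in members[i]:
                for b in members[j]:
                    score = cross_family_mean
                    if noise_sd > 0:
                        noise = rng.normal(0.0, noise_sd)
                        score += float(
                            np.clip(noise, -2 * noise_sd, 2 * noise_sd)
                        )
                    graph.add_edge(a, b, score=max(score, 0.0))
    return graph


# ---------------------------------------------------------------------------
# Bootstrap-replicate stand-in: NNI topology perturbation
# ---------------------------------------------------------------------------


def perturb_tree(tree: Tree, n_nni: int, seed: int = 0) -> Tree:
    """Apply ``n_nni`` nearest-neighbour interchanges at uniformly chosen
    internal edges of the unrooted topology. Leaf set is unchanged."""
    if n_nni < 0:
        raise ValueError("n_nni must be >= 0")
    if n_nni == 0:
        return tree.copy()
    if len(tree.leaves()) < 4:
        raise ValueError("NNI requires at least 4 leaves")

    # unrooted adjacency with edge lengths
    adj: dict[int, dict[int, float | None]] = {}
    labels: dict[int, str | None] = {}
    ids = itertools.count()
    node_id: dict[int, int] = {}
    for node in tree.preorder():
        node_id[id(node)] = next(ids)
        labels[node_id[id(node)]] = node.label if node.is_leaf else None
        adj[node_id[id(node)]] = {}
    for node in tree.preorder():
        for child in node.children:
            u, v = node_id[id(node)], node_id[id(child)]
            adj[u][v] = child.length
            adj[v][u] = child.length
    # suppress a degree-2 base (rooted input)
    for u in list(adj):
        if len(adj[u]) == 2:
            (a, la), (b, lb) = adj[u].items()
            length = None
            if la is not None or lb is not None:
                length = (la or 0.0) + (lb or 0.0)
            del adj[u]
            del adj[a][u]
            del adj[b][u]
            adj[a][b] = length
            adj[b][a] = length

    rng = np.random.default_rng(seed)
    for _ in range(n_nni):
        internal_edges = sorted(
            (u, v)
            for u in adj
            for v in adj[u]
            if u < v and len(adj[u]) >= 3 and len(adj[v]) >= 3
        )
        if not internal_edges:
            break
        u, v = internal_edges[rng.integers(len(internal_edges))]
        xs = sorted(n for n in adj[u] if n != v)
        ys = sorted(n for n in adj[v] if n != u)
        x = xs[rng.integers(len(xs))]
        y = ys[rng.integers(len(ys))]
        lx, ly = adj[u][x], adj[v][y]
        del adj[u][x], adj[x][u], adj[v][y], adj[y][v]
        adj[u][y] = ly
        adj[y][u] = ly
        adj[v][x] = lx
        adj[x][v] = lx

    # rebuild a rooted representation (arbitrary base at the neighbour of the
    # smallest leaf, for determinism)
    smallest = min(
        (lbl, nid) for nid, lbl in labels.items() if lbl is not None and nid in adj
    )[1]
    base = next(iter(adj[smallest]))

    def build(nid: int, parent: int | None) -> Node:
        node = Node(labels.get(nid))
        for nbr, length in sorted(adj[nid].items()):
            if nbr == parent:
                continue
            child = build(nbr, nid)
            child.length = length
            node.add_child(child)
        return node

    return Tree(build(base, None), rooted=False)
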