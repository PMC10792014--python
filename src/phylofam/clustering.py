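"""Similarity-graph homology clustering at graduated stringency thresholds.

Sequences are vertices; undirected edges carry a P-value (E-values from
BLAST tabular input are used as P-value surrogates after capping at 1).
Homology groups are the connected components of the subgraph restricted to
edges with ``P <= threshold``; relaxing the threshold can only merge
components, never split them, which gives the nested "threshold ladder"
used to delineate groups and track when they fuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SimilarityGraph",
    "Partition",
    "build_graph",
    "components_at",
    "merge_threshold",
    "threshold_profile",
    "component_annotations",
    "layout2d",
    "write_blast_tsv",
]

_P_FLOOR = 1e-300  # zero E-values are clamped here so -log10 stays finite


class SimilarityGraph:
    """Undirected similarity graph with one edge per unordered pair."""

    def __init__(self):
        self._g = nx.Graph()

    def add_vertex(self, vid: str, **attrs) -> None:
        self._g.add_node(vid, **attrs)

    def add_edge(self, u: str, v: str, p: float | None = None,
                 score: float | None = None) -> None:
        """Add an edge given either a P-value or a ``-log10 P`` score."""
        if u == v:
            raise ValueError(f"self-edge on {u!r}")
        if (p is None) == (score is None):
            raise ValueError("give exactly one of p= or score=")
        if p is None:
            p = 10.0 ** (-score)
        p = min(max(p, _P_FLOOR), 1.0)
        self._g.add_edge(u, v, p=p)

    @property
    def vertices(self) -> list[str]:
        return sorted(self._g.nodes)

    def vertex_attrs(self, vid: str) -> dict:
        return self._g.nodes[vid]

    def edges(self) -> list[tuple[str, str, float]]:
        return [
            (min(u, v), max(u, v), d["p"]) for u, v, d in self._g.edges(data=True)
        ]

    def p_value(self, u: str, v: str) -> float:
        return self._g.edges[u, v]["p"]

    def score(self, u: str, v: str) -> float:
        return -np.log10(self._g.edges[u, v]["p"])

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def subgraph_at(self, threshold: float) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._g.nodes)
        g.add_edges_from(
            (u, v) for u, v, d in self._g.edges(data=True) if d["p"] <= threshold
        )
        return g


@dataclass
class Partition:
    """Connected components of the graph thresholded at ``threshold``."""

    threshold: float
    assignment: dict[str, int]

    def groups(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for vid, cid in self.assignment.items():
            out.setdefault(cid, set()).add(vid)
        return {cid: frozenset(members) for cid, members in out.items()}

    def n_components(self) -> int:
        return len(set(self.assignment.values()))

    def refines(self, other: "Partition") -> bool:
        """True if every component here is contained in one of ``other``."""
        for members in self.groups().values():
            targets = {other.assignment[v] for v in members}
            if len(targets) != 1:
                return False
        return True


def build_graph(rows, dedup_policy: str = "min") -> SimilarityGraph:
    """Build a graph from BLAST outfmt-6-like rows.

    ``rows`` is a path to a TSV file or an iterable of already-split rows.
    Only the query id, subject id and E-value columns are consumed
    (columns 1, 2 and 11 of the 12-column layout; a minimal 3-column
    ``query<TAB>subject<TAB>evalue`` layout is also accepted). Self-hits are
    dropped; A->B / B->A asymmetry is collapsed per ``dedup_policy``
    (``min`` | ``max`` | ``mean`` over the two P-values).
    """
    if dedup_policy not in ("min", "max", "mean"):
        raise ValueError(f"unknown dedup policy {dedup_policy!r}")

    if isinstance(rows, str):
        with open(rows) as handle:
            parsed = [line.rstrip("\n").split("\t") for line in handle if line.strip()]
    else:
        parsed = [list(r) for r in rows]

    pair_values: dict[tuple[str, str], list[float]] = {}
    vertices: set[str] = set()
    for lineno, cols in enumerate(parsed, start=1):
        if len(cols) >= 11:
            q, s, raw = cols[0], cols[1], cols[10]
        elif len(cols) == 3:
            q, s, raw = cols
        else:
            raise ValueError(f"line {lineno}: expected 3 or >=11 columns, got {len(cols)}")
        try:
            value = float(raw)
        except ValueError:
            raise ValueError(f"line {lineno}: unparseable E-value {raw!r}") from None
        vertices.add(q)
        vertices.add(s)
        if q == s:
            continue
        pair_values.setdefault((min(q, s), max(q, s)), []).append(value)

    graph = SimilarityGraph()
    for vid in sorted(vertices):
        graph.add_vertex(vid)
    reduce = {"min": min, "max": max, "mean": lambda xs: sum(xs) / len(xs)}[dedup_policy]
    for (u, v), values in pair_values.items():
        graph.add_edge(u, v, p=reduce(values))
    return graph


def components_at(graph: SimilarityGraph, threshold: float) -> Partition:
    """Partition into connected components using edges with ``P <= threshold``.

    Component ids are assigned by smallest member vertex, so output is
    stable across runs. Isolated vertices form singleton components.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph.subgraph_at(threshold))),
        key=lambda c: c[0],
    )
    assignment = {}
    for cid, members in enumerate(comps):
        for vid in members:
            assignment[vid] = cid
    return Partition(threshold, assignment)


def merge_threshold(
    graph: SimilarityGraph, set_a: set[str], set_b: set[str]
) -> float | None:
    """Smallest threshold at which some vertex of A and some vertex of B
    fall into one component: the minimax (bottleneck) edge P-value over all
    A-B paths. ``None`` if A and B are never connected."""
    set_a, set_b = set(set_a), set(set_b)
    if not set_a or not set_b:
        raise ValueError("sets must be non-empty")
    if set_a & set_b:
        raise ValueError("sets must be disjoint")

    parent: dict[str, str] = {v: v for v in graph.vertices}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = sorted(graph.edges(), key=lambda e: e[2])
    i = 0
    while i < len(edges):
        p = edges[i][2]
        while i < len(edges) and edges[i][2] == p:
            u, v, _ = edges[i]
            parent[find(u)] = find(v)
            i += 1
        roots_a = {find(x) for x in set_a}
        if roots_a & {find(x) for x in set_b}:
            return p
    return None


def threshold_profile(
    graph: SimilarityGraph, thresholds: list[float]
) -> list[Partition]:
    """One partition per threshold, strictest (smallest P) first.

    Raises on an unsorted ladder; each partition provably refines all
    looser ones.
    """
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing (strictest first)")
    return [components_at(graph, t) for t in thresholds]


def component_annotations(
    graph: SimilarityGraph, partition: Partition, annotations: dict[str, str]
) -> dict[int, str | None]:
    """Name each component by majority vote over its annotated members
    (e.g., genes of reference species); ties break lexicographically; a
    component with no annotated member gets ``None``."""
    out: dict[int, str | None] = {}
    for cid, members in partition.groups().items():
        votes: dict[str, int] = {}
        for vid in members:
            if vid in annotations:
                votes[annotations[vid]] = votes.get(annotations[vid], 0) + 1
        if votes:
            best = max(votes.items(), key=lambda kv: (kv[1], ))
            winners = sorted(k for k, n in votes.items() if n == best[1])
            out[cid] = winners[0]
        else:
            out[cid] = None
    return out


def layout2d(
    graph: SimilarityGraph, iterations: int = 500, seed: int = 0
) -> dict[str, tuple[float, float]]:
    """Toy deterministic force-directed 2-D embedding (visual aid only).

    Edges attract proportionally to their ``-log10 P`` score; all pairs
    repel with an inverse-square term. ``iterations=0`` returns the seeded
    random initial coordinates unchanged.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    vertices = graph.vertices
    n = len(vertices)
    index = {v: i for i, v in enumerate(vertices)}
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-1.0, 1.0, size=(n, 2))
    if n > 1 and iterations > 0:
        attract = np.zeros((n, n))
        for u, v, _p in graph.edges():
            s = graph.score(u, v)
            attract[index[u], index[v]] = s
            attract[index[v], index[u]] = s
        attract /= max(attract.max(), 1.0)
        step = 0.05
        for _ in range(iterations):
            diff = pos[None, :, :] - pos[:, None, :]  # diff[i,j] = pos[j]-pos[i]
            dist2 = (diff ** 2).sum(axis=2) + 1e-9
            np.fill_diagonal(dist2, np.inf)
            repulse = diff / dist2[:, :, None]
            force = (attract[:, :, None] * diff).sum(axis=1)
            force -= 0.01 * repulse.sum(axis=1)
            pos += step * force
    return {v: (float(pos[i, 0]), float(pos[i, 1])) for v, i in index.items()}


def write_blast_tsv(graph: SimilarityGraph, path: str) -> None:
    """Write edges as 12-column BLAST outfmt-6-like rows (placeholder values
    everywhere except query, subject and E-value)."""
    with open(path, "w") as handle:
        for u, v, p in sorted(graph.edges()):
            handle.write(
                "\t".join(
                    [u, v, "100.0", "0", "0", "0", "0", "0", "0", "0",
                     f"{p:.6g}", "0.0"]
                )
                + "\n"
            )
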