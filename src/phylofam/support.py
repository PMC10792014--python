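"""Branch support from replicate trees: Transfer Bootstrap Expectation (TBE)
and Felsenstein bootstrap proportion (FBP), plus the traffic-light
classification used in figure annotation.

For a reference branch with bipartition b = (A|B), lighter side p = min(|A|,
|B|), the transfer index against a replicate is the minimum number of leaves
that must be moved to turn some replicate branch into b; the per-replicate
support is 1 - delta/(p-1) and TBE is its mean over replicates. FBP is the
fraction of replicates containing b exactly. Both are invariant to rooting
and replicate order, and TBE >= FBP always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import Node, Tree

__all__ = [
    "BranchSupport",
    "bipartitions",
    "transfer_index",
    "tbe",
    "fbp",
    "evaluate_support",
    "classify_support",
    "annotate_tree",
]


@dataclass
class BranchSupport:
    bipartition: frozenset[str]  # the side not containing the reference leaf
    p: int  # lighter-side size
    tbe: float
    fbp: float
    n_replicates: int


def _clades(tree: Tree) -> list[frozenset[str]]:
    """Leaf set under every node except the root (one per edge)."""
    sets: dict[int, frozenset[str]] = {}
    out = []
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = frozenset([node.label])
        else:
            sets[id(node)] = frozenset().union(
                *(sets[id(c)] for c in node.children)
            )
        if node.parent is not None:
            out.append(sets[id(node)])
    return out


def _normalise(side: frozenset[str], leaves: frozenset[str], ref: str):
    return leaves - side if ref in side else side


def bipartitions(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted topology, one per internal
    branch; each is represented by the side not containing the smallest
    leaf label. Empty for trees with < 4 leaves."""
    leaves = frozenset(tree.leaf_labels())
    if len(leaves) < 4:
        return set()
    ref = min(leaves)
    out = set()
    for clade in _clades(tree):
        if 2 <= len(clade) <= len(leaves) - 2:
            out.add(_normalise(clade, leaves, ref))
    return out


def transfer_index(bip: frozenset[str], replicate: Tree) -> int:
    """Minimum number of leaf moves turning some replicate branch (any
    branch, pendant ones included) into ``bip``. Zero iff ``bip`` occurs in
    the replicate; at most ``p - 1``."""
    leaves = sorted(replicate.leaf_labels())
    leafset = frozenset(leaves)
    if not bip < leafset:
        raise ValueError("replicate leaf set does not match the reference")
    n = len(leaves)
    index = {label: i for i, label in enumerate(leaves)}
    target = np.zeros(n, dtype=bool)
    for label in bip:
        target[index[label]] = True
    best = n
    for clade in _clades(replicate):
        vec = np.zeros(n, dtype=bool)
        for label in clade:
            vec[index[label]] = True
        d = int(np.count_nonzero(vec != target))
        best = min(best, d, n - d)
        if best == 0:
            break
    return best


def _check_replicates(ref_tree: Tree, replicates: list[Tree]) -> frozenset[str]:
    if not replicates:
        raise ValueError("at least one replicate tree is required")
    leafset = frozenset(ref_tree.leaf_labels())
    for k, rep in enumerate(replicates):
        if frozenset(rep.leaf_labels()) != leafset:
            raise ValueError(f"replicate {k} has a different leaf set")
    return leafset


def evaluate_support(ref_tree: Tree, replicates: list[Tree]) -> list[BranchSupport]:
    """TBE and FBP for every non-trivial branch of the reference tree."""
    leafset = _check_replicates(ref_tree, replicates)
    ref = min(leafset)
    ref_bips = sorted(bipartitions(ref_tree), key=sorted)
    rep_bips = [bipartitions(rep) for rep in replicates]
    out = []
    for bip in ref_bips:
        p = min(len(bip), len(leafset) - len(bip))
        values = []
        hits = 0
        for rep, bips in zip(replicates, rep_bips):
            if bip in bips:
                values.append(1.0)
                hits += 1
            else:
                delta = transfer_index(bip, rep)
                values.append(1.0 - delta / (p - 1))
        out.append(
            BranchSupport(
                bipartition=bip,
                p=p,
                tbe=float(np.mean(values)),
                fbp=hits / len(replicates),
                n_replicates=len(replicates),
            )
        )
    return out


def tbe(ref_tree: Tree, replicates: list[Tree]) -> dict[frozenset[str], float]:
    return {b.bipartition: b.tbe for b in evaluate_support(ref_tree, replicates)}


def fbp(ref_tree: Tree, replicates: list[Tree]) -> dict[frozenset[str], float]:
    return {b.bipartition: b.fbp for b in evaluate_support(ref_tree, replicates)}


@dataclass(frozen=True)
class SupportScheme:
    """Traffic-light thresholds (module defaults, not paper-derived)."""

    high: float = 0.90
    intermediate: float = 0.70


def classify_support(value: float, scheme: SupportScheme = SupportScheme()) -> str:
    """Classify a support value as high / intermediate / low.

    Values in [0, 1] are read on the proportion scale; values in (1, 100]
    as percentages.
    """
    if value < 0 or value > 100:
        raise ValueError(f"support value {value} out of range")
    if value > 1.0:
        value /= 100.0
    if value >= scheme.high:
        return "high"
    if value >= scheme.intermediate:
        return "intermediate"
    return "low"


def annotate_tree(ref_tree: Tree, supports: list[BranchSupport]) -> Tree:
    """Copy of the reference tree with ``TBE/FBP`` internal labels."""
    leaves = frozenset(ref_tree.leaf_labels())
    ref = min(leaves)
    by_bip = {b.bipartition: b for b in supports}
    out = ref_tree.copy()
    sets: dict[int, frozenset[str]] = {}
    seen: set[frozenset[str]] = set()
    for node in out.postorder():
        if node.is_leaf:
            sets[id(node)] = frozenset([node.label])
            continue
        sets[id(node)] = frozenset().union(*(sets[id(c)] for c in node.children))
        if node.parent is None:
            continue
        bip = _normalise(sets[id(node)], leaves, ref)
        rec = by_bip.get(bip)
        # both root-child edges induce the same bipartition; label it once
        if rec is not None and bip not in seen:
            seen.add(bip)
            node.label = f"{rec.tbe:.3f}/{rec.fbp:.3f}"
    return out
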