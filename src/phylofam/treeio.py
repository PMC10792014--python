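"""Tree containers and Newick I/O.

Supports the Newick dialect produced by common tree-inference programs:
internal node labels after ``)``, branch lengths after ``:``, square-bracket
comments ignored except ``[&&NHX:...]`` blocks, which are parsed into a
per-node dict and written back verbatim on serialisation.

Two tree roles are distinguished downstream:

* a *species tree* (:class:`SpeciesTree`) must be rooted, strictly binary,
  and carry unique non-empty labels on every node (unlabelled internal nodes
  are auto-named deterministically);
* a *gene tree* is any :class:`Tree`; it may be unrooted (stored with a
  multifurcating base) and may contain polytomies, which must be resolved
  before reconciliation.
"""

from __future__ import annotations

from typing import Callable, Iterator


class TreeError(Exception):
    """Base class for tree-related errors."""


class NewickParseError(TreeError):
    """Malformed Newick input; ``offset`` is the character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class ValidationError(TreeError):
    """Tree violates a structural invariant."""


class LeafMapError(TreeError):
    """Gene-tree leaves cannot be mapped onto species-tree leaves."""


class Node:
    """A tree node. ``label`` is None for anonymous internal nodes."""

    __slots__ = ("label", "length", "nhx", "parent", "children")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        nhx: dict[str, str] | None = None,
    ):
        self.label = label
        self.length = length
        self.nhx = nhx
        self.parent: Node | None = None
        self.children: list[Node] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind}>"


class Tree:
    """A rooted container; ``rooted=False`` marks an arbitrary base."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def __len__(self) -> int:
        return sum(1 for _ in self.preorder())

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length,
                       dict(node.nhx) if node.nhx else None)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root), rooted=self.rooted)

    def find(self, label: str) -> Node:
        for node in self.preorder():
            if node.label == label:
                return node
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------------

_LABEL_TERMINATORS = set("(),:;[\t\n\r ")


class _Parser:
    def __init__(self, text: str):
        self.s = text
        self.i = 0

    def error(self, message: str) -> None:
        raise NewickParseError(message, self.i)

    def peek(self) -> str:
        return self.s[self.i] if self.i < len(self.s) else ""

    def skip_space(self) -> None:
        while self.i < len(self.s) and self.s[self.i] in " \t\n\r":
            self.i += 1

    def read_comment(self, node: Node) -> None:
        """Consume a ``[...]`` comment; keep NHX content on ``node``."""
        start = self.i
        depth = 0
        while self.i < len(self.s):
            c = self.s[self.i]
            if c == "[":
                depth += 1
            elif c == "]":
                depth -= 1
                if depth == 0:
                    body = self.s[start + 1 : self.i]
                    self.i += 1
                    if body.startswith("&&NHX"):
                        node.nhx = _parse_nhx(body)
                    return
            self.i += 1
        self.i = start
        self.error("unterminated '[' comment")

    def read_label(self) -> str:
        start = self.i
        while self.i < len(self.s) and self.s[self.i] not in _LABEL_TERMINATORS:
            self.i += 1
        return self.s[start:self.i]

    def read_length(self) -> float:
        start = self.i
        while self.i < len(self.s) and (
            self.s[self.i].isdigit() or self.s[self.i] in "+-.eE"
        ):
            self.i += 1
        token = self.s[start:self.i]
        try:
            return float(token)
        except ValueError:
            self.i = start
            self.error(f"invalid branch length {token!r}")
            raise AssertionError  # pragma: no cover

    def subtree(self) -> Node:
        self.skip_space()
        node = Node()
        if self.peek() == "(":
            self.i += 1
            while True:
                node.add_child(self.subtree())
                self.skip_space()
                c = self.peek()
                if c == ",":
                    self.i += 1
                    continue
                if c == ")":
                    self.i += 1
                    break
                self.error("expected ',' or ')'")
            if len(node.children) < 2:
                self.error("internal node with fewer than 2 children")
        self.skip_space()
        if self.peek() == "[":
            self.read_comment(node)
        label = self.read_label()
        if label:
            node.label = label
        self.skip_space()
        if self.peek() == "[":
            self.read_comment(node)
        if self.peek() == ":":
            self.i += 1
            node.length = self.read_length()
        self.skip_space()
        if self.peek() == "[":
            self.read_comment(node)
        if node.is_leaf and node.label is None:
            self.error("leaf without a label")
        return node

    def parse(self) -> Node:
        self.skip_space()
        if self.peek() != "(" and not self.peek():
            self.error("empty input")
        root = self.subtree()
        self.skip_space()
        if self.peek() != ";":
            self.error("expected ';'")
        self.i += 1
        self.skip_space()
        if self.i != len(self.s):
            self.error("trailing characters after ';'")
        return root


def _parse_nhx(body: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in body[len("&&NHX"):].split(":"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key] = value
    return out


def parse_newick(text: str, expect_rooted: bool = True) -> Tree:
    """Parse a single Newick tree.

    ``expect_rooted=False`` marks the result as unrooted (arbitrary base);
    downstream consumers must root it explicitly before reconciliation.
    Duplicate leaf labels are rejected.
    """
    if not text or not text.strip():
        raise NewickParseError("empty input", 0)
    root = _Parser(text.rstrip("\n")).parse()
    tree = Tree(root, rooted=expect_rooted)
    labels = tree.leaf_labels()
    if len(labels) != len(set(labels)):
        seen: set[str] = set()
        dup = next(l for l in labels if l in seen or seen.add(l))
        raise ValidationError(f"duplicate leaf label {dup!r}")
    return tree


def parse_newick_file(path: str, expect_rooted: bool = True) -> list[Tree]:
    """Parse a multi-Newick file (one tree per line; blank lines skipped)."""
    trees = []
    with open(path) as handle:
        for line in handle:
            if line.strip():
                trees.append(parse_newick(line, expect_rooted=expect_rooted))
    return trees


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def _min_leaf(node: Node, cache: dict[int, str]) -> str:
    key = id(node)
    if key not in cache:
        if node.is_leaf:
            cache[key] = node.label or ""
        else:
            cache[key] = min(_min_leaf(c, cache) for c in node.children)
    return cache[key]


def write_newick(tree: Tree, canonical: bool = True) -> str:
    """Serialise to Newick. With ``canonical=True`` children are ordered by
    their smallest descendant leaf label, making output reproducible
    (child order carries no meaning)."""
    cache: dict[int, str] = {}

    def fmt(node: Node) -> str:
        parts = ""
        if not node.is_leaf:
            children = node.children
            if canonical:
                children = sorted(children, key=lambda c: _min_leaf(c, cache))
            parts = "(" + ",".join(fmt(c) for c in children) + ")"
        out = parts + (node.label or "")
        if node.length is not None:
            out += f":{node.length!r}"
        if node.nhx:
            body = ":".join(f"{k}={v}" for k, v in node.nhx.items())
            out += f"[&&NHX:{body}]"
        return out

    return fmt(tree.root) + ";"


def write_newick_file(trees: list[Tree], path: str, canonical: bool = True) -> None:
    with open(path, "w") as handle:
        for tree in trees:
            handle.write(write_newick(tree, canonical=canonical) + "\n")


def canonical_topology(tree: Tree):
    """Nested-tuple topology fingerprint, invariant to child order."""

    def key(node: Node):
        if node.is_leaf:
            return node.label
        return tuple(sorted((key(c) for c in node.children), key=str))

    return key(tree.root)


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


class SpeciesTree:
    """Validated rooted binary species tree with fast ancestry queries.

    Validation enforces: exactly-binary internal nodes, unique labels, and
    non-empty labels everywhere (anonymous internal nodes are auto-named
    ``node_1``, ``node_2``, ... in preorder).
    """

    def __init__(self, tree: Tree):
        if not tree.rooted:
            raise ValidationError("species tree must be rooted")
        for node in tree.preorder():
            if node.children and len(node.children) != 2:
                raise ValidationError(
                    f"species tree must be binary; node "
                    f"{node.label or '<anonymous>'} has {len(node.children)} children"
                )
        counter = 0
        taken = {n.label for n in tree.preorder() if n.label}
        for node in tree.preorder():
            if not node.label:
                counter += 1
                while f"node_{counter}" in taken:
                    counter += 1
                node.label = f"node_{counter}"
                taken.add(node.label)
        labels = [n.label for n in tree.preorder()]
        if len(labels) != len(set(labels)):
            seen: set[str] = set()
            dup = next(l for l in labels if l in seen or seen.add(l))
            raise ValidationError(f"duplicate node label {dup!r}")

        self.tree = tree
        self._by_label: dict[str, Node] = {n.label: n for n in tree.preorder()}
        self._depth: dict[int, int] = {}
        self._tin: dict[int, int] = {}
        self._tout: dict[int, int] = {}
        clock = 0
        for node in tree.preorder():
            parent = node.parent
            self._depth[id(node)] = 0 if parent is None else self._depth[id(parent)] + 1
            self._tin[id(node)] = clock
            clock += 1
        for node in tree.postorder():
            self._tout[id(node)] = (
                self._tin[id(node)]
                if node.is_leaf
                else max(self._tout[id(c)] for c in node.children)
            )

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return cls(parse_newick(text, expect_rooted=True))

    @property
    def root(self) -> Node:
        return self.tree.root

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def node(self, label: str) -> Node:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no species-tree node labelled {label!r}") from None

    def leaf_labels(self) -> list[str]:
        return self.tree.leaf_labels()

    def node_labels(self) -> list[str]:
        return [n.label for n in self.tree.preorder()]

    def depth(self, node: Node) -> int:
        return self._depth[id(node)]

    def is_ancestor_or_equal(self, anc: Node, desc: Node) -> bool:
        return (
            self._tin[id(anc)] <= self._tin[id(desc)]
            and self._tout[id(desc)] <= self._tout[id(anc)]
        )

    def lca(self, a: Node, b: Node) -> Node:
        while not self.is_ancestor_or_equal(a, b):
            a = a.parent
        return a

    def lca_of(self, nodes: list[Node]) -> Node:
        out = nodes[0]
        for node in nodes[1:]:
            out = self.lca(out, node)
        return out

    def path_length(self, anc: Node, desc: Node) -> int:
        """Number of edges on the (directed) path from ``anc`` down to ``desc``."""
        if not self.is_ancestor_or_equal(anc, desc):
            raise ValueError(
                f"{anc.label!r} is not an ancestor of {desc.label!r}"
            )
        return self._depth[id(desc)] - self._depth[id(anc)]

    def edges(self) -> Iterator[tuple[Node, Node]]:
        """Yield (parent, child) pairs; edges are identified downstream by
        the child node's label."""
        for node in self.tree.preorder():
            for child in node.children:
                yield node, child

    def ancestors_or_equal(self, node: Node) -> list[Node]:
        out = [node]
        while out[-1].parent is not None:
            out.append(out[-1].parent)
        return out


# ---------------------------------------------------------------------------
# Leaf -> species mapping
# ---------------------------------------------------------------------------


def leaf_species_map(
    gene_tree: Tree,
    species_tree: SpeciesTree,
    separator: str = "_",
    position: str = "prefix",
) -> dict[str, str]:
    """Extract the species token from every gene-tree leaf label.

    ``position`` selects whether the species token precedes (``prefix``) or
    follows (``suffix``) the first/last occurrence of ``separator``. All
    problems are reported at once.
    """
    if position not in ("prefix", "suffix"):
        raise ValueError("position must be 'prefix' or 'suffix'")
    mapping: dict[str, str] = {}
    problems: list[str] = []
    for leaf in gene_tree.leaves():
        label = leaf.label
        if separator not in label:
            problems.append(f"leaf {label!r} lacks separator {separator!r}")
            continue
        if position == "prefix":
            species = label.split(separator, 1)[0]
        else:
            species = label.rsplit(separator, 1)[1]
        if species not in species_tree:
            problems.append(f"leaf {label!r}: unknown species {species!r}")
            continue
        mapping[label] = species
    if problems:
        raise LeafMapError("; ".join(problems))
    return mapping


def species_map_from_function(
    gene_tree: Tree, species_tree: SpeciesTree, fn: Callable[[str], str]
) -> dict[str, str]:
    """Build a leaf->species map from an arbitrary callable (e.g., to force
    host-species overrides for xenologous sequences)."""
    mapping = {}
    for leaf in gene_tree.leaves():
        species = fn(leaf.label)
        if species not in species_tree:
            raise LeafMapError(f"leaf {leaf.label!r}: unknown species {species!r}")
        mapping[leaf.label] = species
    return mapping
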