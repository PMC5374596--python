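"""Rooted binary trees, Newick I/O, and ancestry queries.

Every downstream module (scenario validation, the reconciliation dynamic
program, the feasibility graph, the repair loop) works on the
:class:`RootedBinaryTree` defined here: an immutable node-labelled rooted
binary tree with parent/children maps and cached traversal orders.  Newick
parsing is delegated to :mod:`dendropy`; the parsed topology is converted to
this structure, validated for binary-ness, and unlabeled internal nodes are
auto-named deterministically.

Branch lengths in the input are parsed and discarded: the reconciliation
model here is undated, so only the topology matters.  A warning is logged
once per process when lengths are dropped.
"""

from __future__ import annotations

import io
import logging
from typing import Dict, List, Mapping, Optional, Tuple

import dendropy

logger = logging.getLogger("reconrepair")

__all__ = [
    "TreeError",
    "NewickParseError",
    "NonBinaryTreeError",
    "LeafMappingError",
    "RootedBinaryTree",
    "parse_newick",
    "write_newick",
    "parse_leaf_mapping",
]


class TreeError(ValueError):
    """Base class for tree-structure errors."""


class NewickParseError(TreeError):
    """Raised when Newick text cannot be parsed."""


class NonBinaryTreeError(TreeError):
    """Raised when a parsed tree has a node with a number of children != 2."""


class LeafMappingError(ValueError):
    """Raised for malformed or incomplete leaf-association tables."""


_warned_branch_lengths = False


class RootedBinaryTree:
    """A rooted tree in which every internal node has exactly two children.

    Nodes are identified by unique string labels.  Children order is
    significant and preserved from the source (e.g. Newick text); every
    "deterministic order" guarantee downstream is defined relative to it.

    Parameters
    ----------
    root:
        Label of the root node.
    children:
        Map from each internal node label to its ordered ``(left, right)``
        pair of child labels.  Labels not appearing as keys are leaves.
    """

    def __init__(self, root: str, children: Mapping[str, Tuple[str, str]]):
        self.root = root
        self.children: Dict[str, Tuple[str, str]] = {
            k: (v[0], v[1]) for k, v in children.items()
        }
        self.parent: Dict[str, str] = {}
        for node, (left, right) in self.children.items():
            for child in (left, right):
                if child in self.parent:
                    raise TreeError(f"node {child!r} has more than one parent")
                self.parent[child] = node
        self._validate()
        self._index()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        if self.root in self.parent:
            raise TreeError(f"root {self.root!r} has a parent")
        for node, pair in self.children.items():
            if len(pair) != 2:
                raise NonBinaryTreeError(
                    f"non-binary tree: node {node!r} has {len(pair)} children"
                )
        # reachability from the root doubles as the acyclicity check
        seen: List[str] = []
        stack = [self.root]
        seen_set = set()
        while stack:
            node = stack.pop()
            if node in seen_set:
                raise TreeError(f"cycle detected at node {node!r}")
            seen_set.add(node)
            seen.append(node)
            if node in self.children:
                stack.extend(reversed(self.children[node]))
        all_nodes = set(self.children) | set(self.parent) | {self.root}
        unreachable = all_nodes - seen_set
        if unreachable:
            raise TreeError(f"nodes unreachable from root: {sorted(unreachable)}")

    def _index(self) -> None:
        # post-order: children (left then right) before parents
        post: List[str] = []
        stack: List[Tuple[str, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node not in self.children:
                post.append(node)
                continue
            stack.append((node, True))
            left, right = self.children[node]
            stack.append((right, False))
            stack.append((left, False))
        self._postorder: Tuple[str, ...] = tuple(post)
        self._postorder_index: Dict[str, int] = {n: i for i, n in enumerate(post)}

        pre: List[str] = []
        stack2 = [self.root]
        while stack2:
            node = stack2.pop()
            pre.append(node)
            if node in self.children:
                left, right = self.children[node]
                stack2.append(right)
                stack2.append(left)
        self._preorder: Tuple[str, ...] = tuple(pre)

        self._depth: Dict[str, int] = {self.root: 0}
        for node in pre[1:]:
            self._depth[node] = self._depth[self.parent[node]] + 1

    # -- basic accessors ------------------------------------------------------

    @property
    def nodes(self) -> Tuple[str, ...]:
        """All node labels, in post-order."""
        return self._postorder

    @property
    def leaves(self) -> Tuple[str, ...]:
        """Leaf labels in post-order (i.e. left-to-right)."""
        return tuple(n for n in self._postorder if n not in self.children)

    @property
    def internal_nodes(self) -> Tuple[str, ...]:
        """Internal node labels in post-order."""
        return tuple(n for n in self._postorder if n in self.children)

    def is_leaf(self, node: str) -> bool:
        self._require(node)
        return node not in self.children

    def children_of(self, node: str) -> Tuple[str, str]:
        self._require(node)
        return self.children[node]

    def parent_of(self, node: str) -> Optional[str]:
        """Parent label, or ``None`` for the root."""
        self._require(node)
        return self.parent.get(node)

    def sibling_of(self, node: str) -> Optional[str]:
        parent = self.parent_of(node)
        if parent is None:
            return None
        left, right = self.children[parent]
        return right if node == left else left

    def depth(self, node: str) -> int:
        self._require(node)
        return self._depth[node]

    def postorder(self) -> Tuple[str, ...]:
        return self._postorder

    def preorder(self) -> Tuple[str, ...]:
        return self._preorder

    def postorder_index(self, node: str) -> int:
        self._require(node)
        return self._postorder_index[node]

    @property
    def height(self) -> int:
        """Maximum root-to-leaf edge count."""
        return max(self._depth[leaf] for leaf in self.leaves)

    def _require(self, node: str) -> None:
        if node not in self._postorder_index:
            raise TreeError(f"unknown node {node!r}")

    # -- ancestry queries -----------------------------------------------------

    def relate(self, x: str, y: str) -> str:
        """Relation of ``x`` to ``y``.

        Returns one of ``"equal"``, ``"ancestor"`` (x >_T y, x != y),
        ``"descendant"`` (x <_T y), or ``"incomparable"``.
        """
        self._require(x)
        self._require(y)
        if x == y:
            return "equal"
        z = self.lca(x, y)
        if z == x:
            return "ancestor"
        if z == y:
            return "descendant"
        return "incomparable"

    def is_ancestor_or_equal(self, x: str, y: str) -> bool:
        """True iff ``x >=_T y`` (x on the path from root to y, inclusive)."""
        return self.relate(x, y) in ("equal", "ancestor")

    def is_strict_ancestor(self, x: str, y: str) -> bool:
        return self.relate(x, y) == "ancestor"

    def incomparable(self, x: str, y: str) -> bool:
        return self.relate(x, y) == "incomparable"

    def lca(self, x: str, y: str) -> str:
        """Least common ancestor: the deepest node that is >=_T both."""
        self._require(x)
        self._require(y)
        while self._depth[x] > self._depth[y]:
            x = self.parent[x]
        while self._depth[y] > self._depth[x]:
            y = self.parent[y]
        while x != y:
            x = self.parent[x]
            y = self.parent[y]
        return x

    def path_length(self, x: str, y: str) -> int:
        """Number of edges on the unique path between ``x`` and ``y``."""
        z = self.lca(x, y)
        return (self._depth[x] - self._depth[z]) + (self._depth[y] - self._depth[z])

    def traversal_stats(self) -> Tuple[Tuple[str, ...], int]:
        """Post-order node sequence and the tree height (in edges)."""
        return self._postorder, self.height

    # -- misc -----------------------------------------------------------------

    def __contains__(self, node: str) -> bool:
        return node in self._postorder_index

    def __len__(self) -> int:
        return len(self._postorder)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RootedBinaryTree({write_newick(self)!r})"


def parse_newick(text: str) -> RootedBinaryTree:
    """Parse a single rooted Newick expression into a :class:`RootedBinaryTree`.

    Internal node labels are optional; unlabeled internal nodes are auto-named
    ``n0, n1, ...`` by pre-order position so that repeated parses of the same
    text produce identical trees.  Branch lengths are discarded (undated
    model).  Polytomies and unary nodes are rejected.
    """
    global _warned_branch_lengths
    if not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    if any(
        edge.length is not None
        for edge in dtree.preorder_edge_iter()
        if edge.head_node is not dtree.seed_node
    ):
        if not _warned_branch_lengths:
            logger.warning("branch lengths present in Newick input are ignored "
                           "(undated reconciliation model)")
            _warned_branch_lengths = True

    def label_of(node: "dendropy.Node") -> Optional[str]:
        if node.taxon is not None and node.taxon.label:
            return str(node.taxon.label)
        if node.label:
            return str(node.label)
        return None

    # deterministic auto-naming by pre-order position
    counter = 0
    names: Dict[int, str] = {}
    used = set()
    for node in dtree.preorder_node_iter():
        lbl = label_of(node)
        if lbl is not None:
            if lbl in used:
                raise NewickParseError(f"duplicate node label {lbl!r}")
            used.add(lbl)
            names[id(node)] = lbl
    for node in dtree.preorder_node_iter():
        if id(node) in names:
            continue
        while f"n{counter}" in used:
            counter += 1
        names[id(node)] = f"n{counter}"
        used.add(f"n{counter}")
        counter += 1

    children: Dict[str, Tuple[str, str]] = {}
    for node in dtree.preorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            continue
        if len(kids) != 2:
            raise NonBinaryTreeError(
                f"non-binary tree: node {names[id(node)]!r} has {len(kids)} children"
            )
        children[names[id(node)]] = (names[id(kids[0])], names[id(kids[1])])

    return RootedBinaryTree(names[id(dtree.seed_node)], children)


def write_newick(tree: RootedBinaryTree) -> str:
    """Serialize a tree to Newick text (labels only, no branch lengths)."""
    out = io.StringIO()

    def emit(node: str) -> None:
        if not tree.is_leaf(node):
            left, right = tree.children_of(node)
            out.write("(")
            emit(left)
            out.write(",")
            emit(right)
            out.write(")")
        out.write(node)

    emit(tree.root)
    out.write(";")
    return out.getvalue()


def parse_leaf_mapping(
    table: str, parasite: RootedBinaryTree, host: RootedBinaryTree
) -> Dict[str, str]:
    """Parse a two-column TSV of parasite-leaf -> host-leaf associations.

    A header row ``parasite<TAB>host`` is auto-detected and skipped.  The map
    must be total over the parasite leaves and land on host leaves; it need
    not be injective or surjective.
    """
    mapping: Dict[str, str] = {}
    rows = [line for line in table.splitlines() if line.strip()]
    for i, line in enumerate(rows):
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise LeafMappingError(
                f"line {i + 1}: expected 2 tab-separated columns, got {len(parts)}"
            )
        p, h = parts[0].strip(), parts[1].strip()
        if i == 0 and (p.lower(), h.lower()) == ("parasite", "host"):
            continue
        if p in mapping:
            raise LeafMappingError(f"duplicate parasite leaf row {p!r}")
        mapping[p] = h
    return validate_leaf_mapping(mapping, parasite, host)


def validate_leaf_mapping(
    mapping: Mapping[str, str], parasite: RootedBinaryTree, host: RootedBinaryTree
) -> Dict[str, str]:
    """Check a leaf map for totality and label validity; return a copy."""
    parasite_leaves = set(parasite.leaves)
    host_leaves = set(host.leaves)
    for p, h in mapping.items():
        if p not in parasite_leaves:
            raise LeafMappingError(f"unknown parasite leaf {p!r}")
        if h not in host_leaves:
            raise LeafMappingError(f"unknown host leaf {h!r}")
    missing = parasite_leaves - set(mapping)
    if missing:
        raise LeafMappingError(f"unmapped parasite leaf {sorted(missing)[0]!r}")
    return dict(mapping)


def format_leaf_mapping(mapping: Mapping[str, str]) -> str:
    """Serialize a leaf map to the two-column TSV format (with header)."""
    lines = ["parasite\thost"]
    lines += [f"{p}\t{h}" for p, h in sorted(mapping.items())]
    return "\n".join(lines) + "\n"
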