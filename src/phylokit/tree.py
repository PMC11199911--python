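"""Core data model for rooted phylogenetic trees and networks.

A tree is a recursive arrangement of :class:`Node` objects wrapped by a
:class:`Tree`.  Each node carries the length of the branch *leading into*
it (``branch_length``), an ordered list of children (any arity —
multifurcations are first-class), an annotation map of key/value metadata
(as written by BEAST, FigTree or NHX-aware tools), and an optional hybrid
tag for phylogenetic networks.

Networks are represented in extended-Newick style: a hybrid node appears
as several ``Node`` records sharing the same ``hybrid_id``.  All traversal
code therefore stays tree-shaped; the records are reunified only by their
identifier.  This mirrors eNewick semantics and avoids a true DAG model.

Node ids are assigned in pre-order (root first, children left to right)
whenever a :class:`Tree` is built or :meth:`Tree.reindex` is called, so
``tree.node_list[k]`` is deterministic and documented.
"""

from __future__ import annotations

from typing import Any, Callable, Iterator, Optional


class TreeError(Exception):
    """Base class for structural and analytical tree errors."""


class TreeStructureError(TreeError):
    """Raised when an operation would corrupt the parent/child structure."""


class Node:
    """A vertex of a rooted tree.

    Parameters
    ----------
    label:
        Taxon or internal-node name; ``None`` when unnamed.
    branch_length:
        Length of the branch leading into this node; ``None`` means the
        length is undefined (it is then omitted when writing).  Negative
        values are tolerated on input (BEAST occasionally produces tiny
        negative lengths) but generated trees always satisfy ``>= 0``.
    """

    __slots__ = (
        "id",
        "label",
        "branch_length",
        "children",
        "parent",
        "_annotation",
        "is_hybrid",
        "hybrid_id",
    )

    def __init__(
        self,
        label: Optional[str] = None,
        branch_length: Optional[float] = None,
    ) -> None:
        self.id: Optional[int] = None
        self.label = label
        self.branch_length = branch_length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self._annotation: Optional[dict[str, Any]] = None
        self.is_hybrid: bool = False
        self.hybrid_id: Optional[str] = None

    # -- annotations -------------------------------------------------

    @property
    def annotation(self) -> dict[str, Any]:
        """Key/value metadata map (created lazily to keep nodes small)."""
        if self._annotation is None:
            self._annotation = {}
        return self._annotation

    @annotation.setter
    def annotation(self, value: dict[str, Any]) -> None:
        self._annotation = dict(value)

    # -- structure ---------------------------------------------------

    def is_leaf(self) -> bool:
        return not self.children

    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "Node") -> None:
        """Append ``child`` to this node's children.

        The child must be detached (no current parent), and must not be an
        ancestor of this node — that would create a cycle.
        """
        if child.parent is not None:
            raise TreeStructureError(
                f"cannot add {child!r}: it already has a parent; detach it first"
            )
        anc: Optional[Node] = self
        while anc is not None:
            if anc is child:
                raise TreeStructureError(
                    f"cannot add {child!r} under {self!r}: it is an ancestor "
                    "of the target (cycle)"
                )
            anc = anc.parent
        self.children.append(child)
        child.parent = self

    def remove_child(self, child: "Node") -> None:
        """Detach ``child`` (and its whole subtree) from this node."""
        for i, c in enumerate(self.children):
            if c is child:
                del self.children[i]
                child.parent = None
                return
        raise TreeStructureError(f"{child!r} is not a child of {self!r}")

    def get_ancestors(self) -> list["Node"]:
        """Ancestors from this node's parent up to and including the root."""
        out: list[Node] = []
        p = self.parent
        while p is not None:
            out.append(p)
            p = p.parent
        return out

    # -- traversal (iterative: deep trees must not hit the call stack) --

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in reversed(node.children))

    def apply_preorder(self, fn: Callable[["Node"], Any]) -> list[Any]:
        """Apply ``fn`` to every node of this subtree in pre-order."""
        return [fn(n) for n in self.preorder()]

    def apply_postorder(self, fn: Callable[["Node"], Any]) -> list[Any]:
        """Apply ``fn`` to every node of this subtree in post-order."""
        return [fn(n) for n in self.postorder()]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        bits = [f"id={self.id}"]
        if self.label is not None:
            bits.append(f"label={self.label!r}")
        if self.branch_length is not None:
            bits.append(f"bl={self.branch_length}")
        if self.is_hybrid:
            bits.append(f"hybrid={self.hybrid_id}")
        return f"Node({', '.join(bits)})"


class Tree:
    """A rooted tree: a root :class:`Node` plus derived node/leaf lists.

    ``node_list`` is the pre-order sequence of all nodes and is cached;
    the manipulation API keeps it current, but code that mutates node
    structure directly must call :meth:`reindex` afterwards.
    """

    __slots__ = ("root", "_node_list")

    def __init__(self, root: Node) -> None:
        if root.parent is not None:
            raise TreeStructureError("tree root must not have a parent")
        self.root = root
        self._node_list: Optional[list[Node]] = None
        self.reindex()

    @property
    def node_list(self) -> list[Node]:
        """All nodes in pre-order; ``node_list[0]`` is the root."""
        if self._node_list is None:
            self.reindex()
        assert self._node_list is not None
        return self._node_list

    @property
    def leaf_list(self) -> list[Node]:
        """Leaves in pre-order (the childless subsequence of node_list)."""
        return [n for n in self.node_list if not n.children]

    def reindex(self) -> None:
        """Recompute the pre-order node list and reassign pre-order ids."""
        nodes = list(self.root.preorder())
        for i, n in enumerate(nodes):
            n.id = i
        self._node_list = nodes

    def invalidate(self) -> None:
        """Drop the cached node list (recomputed lazily on next access)."""
        self._node_list = None

    def contains(self, node: Node) -> bool:
        """True if ``node`` is reachable from this tree's root."""
        anc: Optional[Node] = node
        while anc.parent is not None:
            anc = anc.parent
        return anc is self.root

    # Convenience delegates so trees read like the field's tree objects
    # (tree.reroot(...), tree.ladderise(), ...).  The implementations
    # live in phylokit.manipulate / phylokit.stats.

    def reroot(self, node: Node, proportion: float = 0.5) -> None:
        from .manipulate import reroot

        reroot(self, node, proportion)

    def ladderise(self) -> None:
        from .manipulate import ladderise

        ladderise(self)

    def get_clade(self, node: Node) -> "Tree":
        from .manipulate import get_clade

        return get_clade(self, node)

    # PhyloJS/IcyTree call this getSubtree; keep the alias.
    get_subtree = get_clade

    def get_mrca(self, nodes) -> Node:
        from .manipulate import get_mrca

        return get_mrca(self, nodes)

    def get_rtt_dist(self) -> dict[str, float]:
        from .stats import get_rtt_dist

        return get_rtt_dist(self)

    def get_branch_lengths(self) -> list[Optional[float]]:
        from .stats import get_branch_lengths

        return get_branch_lengths(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree(n_nodes={len(self.node_list)}, n_leaves={len(self.leaf_list)})"


# ---------------------------------------------------------------------
# Structure utilities
# ---------------------------------------------------------------------


def copy_subtree(node: Node) -> Node:
    """Deep, iterative copy of the subtree rooted at ``node``.

    The copy is fully independent: child lists and annotation maps are
    duplicated (annotation list values copied one level deep).
    """

    def clone(n: Node) -> Node:
        c = Node(n.label, n.branch_length)
        c.is_hybrid = n.is_hybrid
        c.hybrid_id = n.hybrid_id
        if n._annotation:
            c._annotation = {
                k: list(v) if isinstance(v, (list, tuple)) else v
                for k, v in n._annotation.items()
            }
        return c

    new_root = clone(node)
    stack = [(node, new_root)]
    while stack:
        orig, copy = stack.pop()
        for child in orig.children:
            cc = clone(child)
            cc.parent = copy
            copy.children.append(cc)
            stack.append((child, cc))
    return new_root


def merge_unary(node: Node) -> Node:
    """Merge a degree-1 (unary) node into its single child.

    Branch lengths are summed where defined (both undefined stays
    undefined); the child's annotations win and the unary node's are
    dropped.  Returns the surviving child, which takes the unary node's
    place (or becomes parentless if the unary node was the root).
    """
    if len(node.children) != 1:
        raise TreeStructureError(f"{node!r} is not unary")
    child = node.children[0]
    lengths = [x for x in (node.branch_length, child.branch_length) if x is not None]
    child.branch_length = sum(lengths) if lengths else None
    node.children = []
    parent = node.parent
    if parent is None:
        child.parent = None
    else:
        for i, c in enumerate(parent.children):
            if c is node:
                parent.children[i] = child
                break
        child.parent = parent
        node.parent = None
    return child


def suppress_unary(tree: Tree) -> None:
    """Remove every degree-1 internal node by merging it into its child."""
    # Post-order so that chains of unary nodes collapse in one pass.
    for node in list(tree.root.postorder()):
        if len(node.children) == 1:
            replacement = merge_unary(node)
            if node is tree.root:
                tree.root = replacement
    tree.reindex()


def trees_equal(
    a: Tree,
    b: Tree,
    *,
    compare_annotations: bool = True,
    rel_tol: float = 0.0,
) -> bool:
    """Structural equality of two trees.

    Compares topology with child order, labels, branch lengths (exactly,
    or to ``rel_tol`` relative tolerance when given), hybrid flags and —
    unless disabled — annotation maps.
    """
    import math

    sa, sb = [a.root], [b.root]
    while sa:
        if not sb:
            return False
        x, y = sa.pop(), sb.pop()
        if x.label != y.label:
            return False
        if (x.branch_length is None) != (y.branch_length is None):
            return False
        if x.branch_length is not None:
            if rel_tol == 0.0:
                if x.branch_length != y.branch_length:
                    return False
            elif not math.isclose(
                x.branch_length, y.branch_length, rel_tol=rel_tol, abs_tol=rel_tol
            ):
                return False
        if x.is_hybrid != y.is_hybrid or x.hybrid_id != y.hybrid_id:
            return False
        if compare_annotations and (x._annotation or {}) != (y._annotation or {}):
            return False
        if len(x.children) != len(y.children):
            return False
        sa.extend(x.children)
        sb.extend(y.children)
    return not sb


def check_integrity(tree: Tree) -> None:
    """Verify structural invariants; raise :class:`TreeStructureError` if broken.

    Checked by full traversal: parent/child bidirectional consistency,
    single-parent membership, pre-order id ordering (parent before child),
    hybrid flag implies hybrid id, and defined branch lengths on the
    cached node list matching a fresh traversal.
    """
    seen: set[int] = set()
    for node in tree.root.preorder():
        if id(node) in seen:
            raise TreeStructureError(f"{node!r} appears twice in the traversal")
        seen.add(id(node))
        for child in node.children:
            if child.parent is not node:
                raise TreeStructureError(
                    f"parent pointer of {child!r} does not match {node!r}"
                )
        if node.is_hybrid and node.hybrid_id is None:
            raise TreeStructureError(f"hybrid node {node!r} lacks a hybrid_id")
    for node in tree.node_list:
        if id(node) not in seen:
            raise TreeStructureError("cached node_list is stale; call reindex()")
        for child in node.children:
            if child.id is not None and node.id is not None and child.id <= node.id:
                raise TreeStructureError("node ids are not a valid pre-order")
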