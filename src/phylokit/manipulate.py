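"""Topological and branch-length operations on trees.

Rerooting here splits a branch: ``reroot(tree, node, proportion)`` places
the new root on the branch *above* ``node``, at ``proportion`` of that
branch measured from the node.  Edges between the old root and the
attachment point are reversed, each branch length travelling with the
edge it subtends, so the leaf set, the total branch length and every
leaf-to-leaf path length are conserved.  The new root's own branch length
is set to 0.0 (so rerooted trees write a trailing ``:0.0``), and an old
root left with a single child is suppressed by merging.

Operations that would cut across a hybrid attachment (reroot on a network,
prune of a clade containing hybrid records) refuse loudly rather than
produce a silently broken network.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Union

from .tree import (
    Node,
    Tree,
    TreeError,
    TreeStructureError,
    copy_subtree,
    merge_unary,
)


def _require_member(tree: Tree, node: Node, what: str) -> None:
    if not tree.contains(node):
        raise TreeError(f"{what}: {node!r} is not a node of this tree")


def reroot(tree: Tree, node: Node, proportion: float = 0.5) -> None:
    """Reroot ``tree`` on the branch above ``node`` (mutates in place).

    ``proportion`` in [0, 1] is the fraction of the split branch assigned
    to ``node``'s side.  Rerooting at the current root is a no-op with a
    warning.  Requires ``node.branch_length`` to be defined (it is the
    branch being split) and refuses to operate on networks.
    """
    _require_member(tree, node, "reroot")
    if node is tree.root:
        warnings.warn("reroot at the current root is a no-op", stacklevel=2)
        return
    if not 0.0 <= proportion <= 1.0:
        raise TreeError(f"reroot proportion must be in [0, 1], got {proportion}")
    if node.branch_length is None:
        raise TreeError("cannot reroot on a branch with undefined length")
    if any(n.is_hybrid for n in tree.node_list):
        raise TreeStructureError("cannot reroot a tree containing hybrid nodes")

    old_parent = node.parent
    assert old_parent is not None
    length = node.branch_length

    # Path from the attachment point up to the old root, with the length
    # of the branch above each path node (the edge to be reversed).
    path = [old_parent] + old_parent.get_ancestors()
    above = [p.branch_length for p in path]

    old_parent.remove_child(node)

    # Reverse the edges along the path: each former parent becomes a
    # child of its former child, keeping the length of the edge between
    # them.
    for i in range(len(path) - 1):
        former_parent = path[i + 1]
        former_parent.children.remove(path[i])
        path[i].children.append(former_parent)
        former_parent.parent = path[i]
        former_parent.branch_length = above[i]

    new_root = Node(branch_length=0.0)
    node.parent = None
    node.branch_length = proportion * length
    new_root.add_child(node)
    old_parent.parent = None
    old_parent.branch_length = (1.0 - proportion) * length
    new_root.add_child(old_parent)

    old_root = path[-1]
    if len(old_root.children) == 1:
        merge_unary(old_root)

    tree.root = new_root
    tree.reindex()


def ladderise(tree: Tree) -> None:
    """Sort children of every node by descendant-leaf count, ascending.

    Ties break on the lexicographically smallest descendant leaf label,
    making the operation deterministic and idempotent.  Only child order
    changes; the leaf set, branch lengths and all path lengths are
    untouched.
    """
    counts: dict[int, int] = {}
    min_label: dict[int, str] = {}
    for node in tree.root.postorder():
        if node.is_leaf():
            counts[id(node)] = 1
            min_label[id(node)] = node.label or ""
        else:
            counts[id(node)] = sum(counts[id(c)] for c in node.children)
            min_label[id(node)] = min(min_label[id(c)] for c in node.children)
    for node in tree.node_list:
        if len(node.children) > 1:
            node.children.sort(key=lambda c: (counts[id(c)], min_label[id(c)]))
    tree.reindex()


def get_clade(tree: Tree, node: Node) -> Tree:
    """Extract the clade rooted at ``node`` as a new, independent Tree.

    The extracted root *retains* its incoming branch length — the branch
    that subtended the clade travels with it.  The copy shares no
    structure with the source: mutating one never affects the other.
    """
    _require_member(tree, node, "get_clade")
    return Tree(copy_subtree(node))


# PhyloJS also exposes this as getSubtree.
get_subtree = get_clade


def get_mrca(tree: Tree, nodes: Iterable[Union[Node, str]]) -> Node:
    """Most recent common ancestor of nodes (or leaf labels).

    The MRCA of a single node is the node itself; the MRCA of all leaves
    is the root.
    """
    items = list(nodes)
    if not items:
        raise TreeError("get_mrca requires at least one node or label")

    by_label: dict[str, Node] = {}
    resolved: list[Node] = []
    for item in items:
        if isinstance(item, str):
            if not by_label:
                for n in tree.node_list:
                    if n.label is not None and n.label not in by_label:
                        by_label[n.label] = n
            try:
                resolved.append(by_label[item])
            except KeyError:
                raise TreeError(f"label {item!r} not found in tree") from None
        else:
            _require_member(tree, item, "get_mrca")
            resolved.append(item)

    mrca = resolved[0]
    for other in resolved[1:]:
        ancestors = {id(mrca)}
        ancestors.update(id(a) for a in mrca.get_ancestors())
        cur: Node = other
        while id(cur) not in ancestors:
            assert cur.parent is not None
            cur = cur.parent
        mrca = cur
    return mrca


def prune(tree: Tree, node: Node) -> Tree:
    """Detach the clade at ``node`` and return it as an independent Tree.

    The detached root keeps its incoming branch length.  A parent left
    unary by the cut is suppressed (branch lengths summed); if that
    parent is the tree root, its surviving child becomes the new root.
    """
    _require_member(tree, node, "prune")
    if node is tree.root:
        raise TreeError("cannot prune the root of the tree")
    if any(n.is_hybrid for n in node.preorder()):
        raise TreeStructureError("cannot prune a clade containing hybrid nodes")

    parent = node.parent
    assert parent is not None
    parent.remove_child(node)
    if len(parent.children) == 1:
        replacement = merge_unary(parent)
        if parent is tree.root:
            tree.root = replacement
    tree.reindex()
    return Tree(node)


def graft(tree: Tree, target: Node, subtree: Tree, branch_length: float) -> None:
    """Attach ``subtree`` as a new child of ``target``.

    The grafted root's incoming branch length is set to ``branch_length``
    (must be non-negative).  The ``subtree`` object should be discarded
    afterwards: its root now belongs to ``tree``.
    """
    _require_member(tree, target, "graft")
    if branch_length < 0:
        raise TreeError(f"graft branch length must be >= 0, got {branch_length}")
    root = subtree.root
    root.branch_length = branch_length
    target.add_child(root)
    tree.reindex()


def random_node(tree: Tree, rng, exclude_root: bool = True) -> Node:
    """Uniformly random node (used by the CLI's random-rerooting mode)."""
    nodes = tree.node_list[1:] if exclude_root else tree.node_list
    return nodes[rng.randrange(len(nodes))]
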