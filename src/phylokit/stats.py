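"""Data extraction and summary statistics for trees.

Covers root-to-tip distances and the root-to-tip regression used for
molecular-clock rate estimation, branch-length extraction, tree length,
the Sackin and Colless imbalance indices, the Pybus–Harvey Gamma
statistic, and the internal/external branch-length ratio (IE ratio).

IE-ratio clade convention
-------------------------
For a clade extracted at node *v*, the branch leading into *v* travels
with the clade and counts towards the *internal* sum.  On the worked
four-taxon tree ``((a:2,b:2):1,(c:1,d:1):4);`` this gives 1/4 = 0.25 for
the {a,b} clade, 4/2 = 2.00 for {c,d}, and — the root's length being
undefined and therefore skipped — 5/6 ≈ 0.83 for the whole tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

import numpy as np

from .tree import Node, Tree, TreeError
from .manipulate import get_clade


@dataclass(frozen=True)
class RegressionResult:
    """Root-to-tip regression fit: distance = slope * time + intercept."""

    slope: float
    intercept: float
    r2: float
    n: int


@dataclass(frozen=True)
class TreeStats:
    """Bundle of whole-tree summaries.

    ``colless`` is None for non-bifurcating trees and ``gamma`` is None
    when the tree is not ultrametric/binary with >= 3 leaves.
    """

    tree_length: float
    sackin: int
    colless: Optional[int]
    gamma: Optional[float]
    ie_ratio: Optional[float]


# ---------------------------------------------------------------------
# Distances and branch lengths
# ---------------------------------------------------------------------


def _leaf_key(node: Node) -> str:
    return node.label if node.label is not None else str(node.id)


def get_rtt_dist(tree: Tree) -> dict[str, float]:
    """Root-to-tip distance for each leaf, keyed by leaf label.

    The root's own (incoming) branch length is excluded.  An undefined
    branch length anywhere on a root-to-leaf path raises, naming the
    first affected leaf.  Unlabelled leaves are keyed by their pre-order
    id.  A single-node tree maps its root to 0.0.
    """
    out: dict[str, float] = {}
    stack: list[tuple[Node, Optional[float]]] = [(tree.root, 0.0)]
    while stack:
        node, dist = stack.pop()
        if node.is_leaf():
            if dist is None:
                raise TreeError(
                    f"undefined branch length on the path to leaf {_leaf_key(node)!r}"
                )
            out[_leaf_key(node)] = dist
            continue
        for child in reversed(node.children):
            if dist is None or child.branch_length is None:
                stack.append((child, None))
            else:
                stack.append((child, dist + child.branch_length))
    return out


def get_branch_lengths(tree: Tree) -> list[Optional[float]]:
    """All branch lengths in pre-order; undefined lengths stay ``None``."""
    return [node.branch_length for node in tree.node_list]


def tree_length(tree: Tree) -> float:
    """Sum of all defined branch lengths."""
    return sum(bl for bl in get_branch_lengths(tree) if bl is not None)


# ---------------------------------------------------------------------
# IE ratio
# ---------------------------------------------------------------------


def ie_ratio(tree: Tree) -> float:
    """Internal-to-external branch-length sum ratio.

    Leaves contribute to the external sum, every other node (including a
    non-leaf root with a defined length) to the internal sum; undefined
    lengths are skipped on both sides.  A zero external sum is an error.
    """
    internal = external = 0.0
    for node in tree.node_list:
        if node.branch_length is None:
            continue
        if node.is_leaf():
            external += node.branch_length
        else:
            internal += node.branch_length
    if external == 0.0:
        raise TreeError("IE ratio undefined: external branch-length sum is zero")
    return internal / external


def format_2dp(value: float) -> str:
    """Two-decimal, half-away-from-zero formatting (JS ``toFixed(2)``)."""
    return str(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def annotate_ie_ratios(tree: Tree) -> None:
    """Annotate every internal node with its clade's IE ratio.

    The value is stored under the key ``ieRatio`` as a two-decimal string
    (clades retain their root's incoming branch length as internal, per
    the module convention).  Leaves are untouched.
    """
    for node in tree.node_list:
        if not node.is_leaf():
            node.annotation["ieRatio"] = format_2dp(ie_ratio(get_clade(tree, node)))


# ---------------------------------------------------------------------
# Imbalance indices
# ---------------------------------------------------------------------


def sackin_index(tree: Tree) -> int:
    """Sum over leaves of topological depth (root depth = 0)."""
    total = 0
    stack: list[tuple[Node, int]] = [(tree.root, 0)]
    while stack:
        node, depth = stack.pop()
        if node.is_leaf():
            total += depth
        else:
            stack.extend((c, depth + 1) for c in node.children)
    return total


def _leaf_counts(tree: Tree) -> dict[int, int]:
    counts: dict[int, int] = {}
    for node in tree.root.postorder():
        counts[id(node)] = (
            1 if node.is_leaf() else sum(counts[id(c)] for c in node.children)
        )
    return counts


def colless_index(tree: Tree) -> int:
    """Sum over internal nodes of |leaves(left) - leaves(right)|.

    Defined only for strictly bifurcating trees; a polytomy (or unary
    node) raises, naming the offending node.
    """
    counts = _leaf_counts(tree)
    total = 0
    for node in tree.node_list:
        if node.is_leaf():
            continue
        if len(node.children) != 2:
            raise TreeError(
                f"Colless index requires a bifurcating tree; {node!r} has "
                f"{len(node.children)} children"
            )
        left, right = node.children
        total += abs(counts[id(left)] - counts[id(right)])
    return total


# ---------------------------------------------------------------------
# Gamma statistic
# ---------------------------------------------------------------------


def _node_heights(tree: Tree) -> dict[int, float]:
    heights: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        if node.branch_length is None:
            raise TreeError(
                "Gamma statistic requires defined branch lengths everywhere"
            )
        heights[id(node)] = heights[id(node.parent)] + node.branch_length
    return heights


def gamma_statistic(tree: Tree, ultrametric_rtol: float = 1e-6) -> float:
    """Pybus–Harvey Gamma for an ultrametric, bifurcating tree.

    With internode intervals ``g_k`` (the duration during which exactly
    ``k`` lineages exist, k = 2..n) and ``T = sum_j j*g_j``::

        gamma = ( (1/(n-2)) * sum_{i=2}^{n-1} sum_{j=2}^{i} j*g_j  -  T/2 )
                / ( T * sqrt(1 / (12*(n-2))) )

    Negative values indicate internal nodes concentrated towards the
    root (an early burst); pure-birth trees give values near zero.  The
    statistic is invariant under global branch-length rescaling.
    Requires n >= 3 leaves, a binary topology and ultrametricity to
    ``ultrametric_rtol`` relative tolerance.
    """
    leaves = tree.leaf_list
    n = len(leaves)
    if n < 3:
        raise TreeError(f"Gamma statistic requires >= 3 leaves, got {n}")
    for node in tree.node_list:
        if node.children and len(node.children) != 2:
            raise TreeError(
                f"Gamma statistic requires a bifurcating tree; {node!r} has "
                f"{len(node.children)} children"
            )
    heights = _node_heights(tree)
    tip_heights = [heights[id(leaf)] for leaf in leaves]
    h_max = max(tip_heights)
    if h_max <= 0:
        raise TreeError("Gamma statistic undefined for a zero-height tree")
    if (h_max - min(tip_heights)) > ultrametric_rtol * h_max:
        raise TreeError(
            "tree is not ultrametric: root-to-tip distances span "
            f"[{min(tip_heights)!r}, {h_max!r}]"
        )

    internal_heights = sorted(
        heights[id(node)] for node in tree.node_list if node.children
    )
    tip_height = sum(tip_heights) / n

    # g[k] is the interval with k lineages; internal_heights[0] is the root.
    g = [0.0] * (n + 1)
    for k in range(2, n):
        g[k] = internal_heights[k - 1] - internal_heights[k - 2]
    g[n] = tip_height - internal_heights[n - 2]

    weighted = [j * g[j] for j in range(2, n + 1)]
    total = sum(weighted)  # T
    if total <= 0:
        raise TreeError("Gamma statistic undefined: total weighted interval is zero")
    prefix = 0.0
    acc = 0.0
    for i in range(2, n):
        prefix += i * g[i]
        acc += prefix
    return (acc / (n - 2) - total / 2.0) / (total * math.sqrt(1.0 / (12.0 * (n - 2))))


# ---------------------------------------------------------------------
# Root-to-tip regression
# ---------------------------------------------------------------------


def rtt_regression(tree: Tree, tip_times: Mapping[str, float]) -> RegressionResult:
    """Ordinary least squares of root-to-tip distance on tip time.

    The slope estimates the molecular-clock rate (distance units per
    time unit) and the intercept extrapolates the distance at time 0.
    Every leaf needs an entry in ``tip_times``, and at least two distinct
    times are required.
    """
    distances = get_rtt_dist(tree)
    try:
        times = np.array([tip_times[label] for label in distances], dtype=float)
    except KeyError as exc:
        raise TreeError(f"no tip time supplied for leaf {exc.args[0]!r}") from None
    dist = np.array(list(distances.values()), dtype=float)
    if len(dist) < 2:
        raise TreeError("root-to-tip regression requires >= 2 tips")
    if np.ptp(times) == 0:
        raise TreeError("root-to-tip regression undefined: all tip times identical")

    slope, intercept = np.polyfit(times, dist, 1)
    residuals = dist - (slope * times + intercept)
    ss_res = float(residuals @ residuals)
    centred = dist - dist.mean()
    ss_tot = float(centred @ centred)
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-300 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return RegressionResult(float(slope), float(intercept), r2, len(dist))


# ---------------------------------------------------------------------
# Convenience bundle
# ---------------------------------------------------------------------


def tree_stats(tree: Tree) -> TreeStats:
    """Compute the whole summary bundle, with None where not applicable."""
    try:
        colless: Optional[int] = colless_index(tree)
    except TreeError:
        colless = None
    try:
        gamma: Optional[float] = gamma_statistic(tree)
    except TreeError:
        gamma = None
    try:
        ratio: Optional[float] = ie_ratio(tree)
    except TreeError:
        ratio = None
    return TreeStats(
        tree_length=tree_length(tree),
        sackin=sackin_index(tree),
        colless=colless,
        gamma=gamma,
        ie_ratio=ratio,
    )
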