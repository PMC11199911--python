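"""Seeded generation of synthetic trees.

These generators exist to exercise the parsers, writers, manipulation
code and statistics at controlled sizes and shapes — from ten tips up to
a million — and to provide the pure-birth ultrametric trees that the
Gamma statistic expects.  Randomness comes exclusively from the
package's portable SplitMix64 generator, so a seed pins the output
byte-for-byte across platforms: the same configuration always writes the
identical Newick string.

Shapes
------
``yule``
    Binary topology built by repeatedly joining two uniformly chosen
    subtrees; every branch gets an exponential length (default mean 1.0).
``caterpillar``
    Fully pectinate (ladder) tree — the worst case for recursive
    parsers, used for deep-nesting stress.
``balanced``
    Perfectly balanced binary tree; requires a power-of-two tip count.

Hybrid injection marks random internal nodes as hybrids and adds a
duplicate ``#H<k>`` reference record elsewhere, giving an
extended-Newick network fixture; no biological model is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from ._rng import SplitMix64
from .tree import Node, Tree

SHAPES = ("yule", "caterpillar", "balanced")


@dataclass
class GeneratorConfig:
    """Knobs for :func:`generate_tree`.

    ``branch_length_mean`` is the mean of the exponential branch-length
    distribution (arbitrary units).  ``hybrid_count`` internal nodes are
    duplicated as extended-Newick hybrid references when positive.
    """

    n_tips: int
    shape: str = "yule"
    branch_length_mean: float = 1.0
    seed: int = 0
    annotate: bool = False
    hybrid_count: int = 0

    def validate(self) -> None:
        if self.n_tips < 1:
            raise ValueError(f"n_tips must be >= 1, got {self.n_tips}")
        if self.shape not in SHAPES:
            raise ValueError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if self.branch_length_mean <= 0:
            raise ValueError("branch_length_mean must be positive")
        if self.hybrid_count < 0:
            raise ValueError("hybrid_count must be >= 0")
        if self.shape == "balanced" and self.n_tips & (self.n_tips - 1):
            raise ValueError("balanced shape requires n_tips to be a power of 2")


def generate_tree(config: Optional[GeneratorConfig] = None, **kwargs) -> Tree:
    """Generate a rooted binary tree with ``n_tips`` leaves ``t1..tN``.

    Accepts either a :class:`GeneratorConfig` or its fields as keyword
    arguments.  The root's branch length is undefined (as in freshly
    parsed trees); every other branch is exponential.  Deterministic
    given the seed.
    """
    if config is None:
        config = GeneratorConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a GeneratorConfig or keyword arguments, not both")
    config.validate()
    rng = SplitMix64(config.seed)
    mean = config.branch_length_mean

    leaves = [
        Node(f"t{i + 1}", rng.exponential(mean)) for i in range(config.n_tips)
    ]
    if config.n_tips == 1:
        root = leaves[0]
        root.branch_length = None
    elif config.shape == "yule":
        root = _join_random(leaves, rng, mean)
    elif config.shape == "caterpillar":
        root = _join_pectinate(leaves, rng, mean)
    else:
        root = _join_balanced(leaves, rng, mean)
    root.branch_length = None
    tree = Tree(root)

    if config.annotate:
        _annotate(tree, rng)
    if config.hybrid_count:
        _inject_hybrids(tree, rng, config.hybrid_count, mean)
    return tree


def _merge(a: Node, b: Node, branch_length: Optional[float]) -> Node:
    parent = Node(branch_length=branch_length)
    parent.children = [a, b]
    a.parent = parent
    b.parent = parent
    return parent


def _join_random(active: list[Node], rng: SplitMix64, mean: float) -> Node:
    def take() -> Node:
        i = rng.randrange(len(active))
        active[i], active[-1] = active[-1], active[i]
        return active.pop()

    while len(active) > 1:
        a, b = take(), take()
        active.append(_merge(a, b, rng.exponential(mean)))
    return active[0]


def _join_pectinate(leaves: list[Node], rng: SplitMix64, mean: float) -> Node:
    cur = _merge(leaves[0], leaves[1], rng.exponential(mean))
    for leaf in leaves[2:]:
        cur = _merge(cur, leaf, rng.exponential(mean))
    return cur


def _join_balanced(level: list[Node], rng: SplitMix64, mean: float) -> Node:
    while len(level) > 1:
        level = [
            _merge(level[i], level[i + 1], rng.exponential(mean))
            for i in range(0, len(level), 2)
        ]
    return level[0]


def _annotate(tree: Tree, rng: SplitMix64) -> None:
    for node in tree.node_list:
        if rng.random() < 0.5:
            node.annotation["rate"] = rng.random()
        if rng.random() < 0.25:
            node.annotation["group"] = f"g{rng.randrange(5) + 1}"


def _inject_hybrids(tree: Tree, rng: SplitMix64, count: int, mean: float) -> None:
    internals = [n for n in tree.node_list if n.children and n is not tree.root]
    count = min(count, len(internals))
    chosen: list[Node] = []
    for _ in range(count):
        i = rng.randrange(len(internals))
        internals[i], internals[-1] = internals[-1], internals[i]
        chosen.append(internals.pop())
    hosts = [n for n in tree.node_list if n.children]
    for k, node in enumerate(chosen, start=1):
        node.is_hybrid = True
        node.hybrid_id = f"H{k}"
        ref = Node(branch_length=rng.exponential(mean))
        ref.is_hybrid = True
        ref.hybrid_id = node.hybrid_id
        hosts[rng.randrange(len(hosts))].add_child(ref)
    tree.reindex()


def generate_ultrametric_tree(
    n_tips: int, seed: int = 0, birth_rate: float = 1.0
) -> Tree:
    """Pure-birth (Yule) ultrametric tree with ``n_tips`` leaves.

    Simulated forward in time with unit-per-lineage birth rate
    ``birth_rate``: the interval during which k lineages exist is
    exponential with mean 1/(k*birth_rate), and the lineage that splits
    is chosen uniformly.  All root-to-tip distances are exactly equal by
    construction.  Leaves are labelled ``t1..tN`` in pre-order.
    """
    if n_tips < 2:
        raise ValueError(f"n_tips must be >= 2, got {n_tips}")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = SplitMix64(seed)

    root = Node()
    first, second = Node(), Node()
    root.children = [first, second]
    first.parent = second.parent = root
    active = [first, second]
    start = {id(first): 0.0, id(second): 0.0}

    height = 0.0
    for k in range(2, n_tips):
        height += rng.exponential(1.0 / (k * birth_rate))
        i = rng.randrange(len(active))
        active[i], active[-1] = active[-1], active[i]
        node = active.pop()
        node.branch_length = height - start.pop(id(node))
        left, right = Node(), Node()
        node.children = [left, right]
        left.parent = right.parent = node
        active.extend((left, right))
        start[id(left)] = start[id(right)] = height
    height += rng.exponential(1.0 / (n_tips * birth_rate))
    for node in active:
        node.branch_length = height - start[id(node)]

    tree = Tree(root)
    for i, leaf in enumerate(tree.leaf_list, start=1):
        leaf.label = f"t{i}"
    return tree


def generate_benchmark_suite(
    sizes: Sequence[int],
    seed: int = 0,
    out_dir: Union[str, Path] = ".",
) -> list[Path]:
    """Write one seeded Yule Newick file per requested size.

    Returns the written paths (``tree_<size>.nwk`` under ``out_dir``).
    Regeneration with the same seed and sizes is byte-identical.
    """
    from .writers import write_newick

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = SplitMix64(seed)
    paths: list[Path] = []
    for size in sizes:
        child_seed = rng.next_uint64()
        tree = generate_tree(n_tips=size, shape="yule", seed=child_seed)
        path = out / f"tree_{size}.nwk"
        path.write_text(write_newick(tree) + "\n")
        paths.append(path)
    return paths
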