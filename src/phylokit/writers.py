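"""Serialise trees to Newick and Nexus.

The writer is iterative (explicit work stack), symmetrical to the parser,
so million-tip trees serialise without recursion-depth failures.  Nodes
with an undefined branch length get no ``:len`` token at all, and
polytomies are written as-is — the writer never resolves them.

Annotations are off by default.  Pass an *annotator* — a callable mapping
a node to a bracketed fragment (or the empty string) — to include them.
The built-in :func:`beast_annotation` and :func:`nhx_annotation` cover
the two common dialects.  A BEAST fragment is placed before the
``:length`` token and an NHX fragment after it, matching where each tool
family writes them; custom annotators follow the same rule (fragments
starting with ``[&&NHX`` go after the length).
"""

from __future__ import annotations

import re
from typing import Any, Callable, Iterable, Optional

from .tree import Node, Tree

Annotator = Callable[[Node], str]

# Characters that force quoting of a Newick label: structural
# punctuation plus anything the tokenizer would treat as whitespace.
_UNSAFE = re.compile(r"[\s()\[\]{}:;,='\"#&]")


def _format_label(label: str) -> str:
    if label and not _UNSAFE.search(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_number(value: float) -> str:
    # Shortest decimal that round-trips; integers without exponent noise.
    if isinstance(value, int):
        return str(value)
    return repr(float(value))


def _format_beast_value(value: Any) -> str:
    if isinstance(value, bool):
        raise ValueError(f"cannot represent boolean annotation value {value!r}")
    if isinstance(value, (int, float)):
        return _format_number(value)
    if isinstance(value, str):
        if '"' in value:
            raise ValueError(f"annotation value {value!r} contains a double quote")
        return f'"{value}"'
    if isinstance(value, (list, tuple)):
        return "{" + ",".join(_format_beast_value(v) for v in value) + "}"
    raise ValueError(f"cannot represent annotation value of type {type(value).__name__}")


def _format_beast_key(key: str) -> str:
    if _UNSAFE.search(key):
        if '"' in key:
            raise ValueError(f"annotation key {key!r} contains a double quote")
        return f'"{key}"'
    return key


def beast_annotation(node: Node) -> str:
    """BEAST/FigTree-style fragment ``[&k=v,k2={a,b}]`` for a node.

    Returns the empty string when the node has no annotations.  Key order
    follows the annotation map's insertion order.  String values are
    always quoted so that numeric-looking text survives a round trip.
    """
    ann = node._annotation
    if not ann:
        return ""
    parts = [f"{_format_beast_key(k)}={_format_beast_value(v)}" for k, v in ann.items()]
    return "[&" + ",".join(parts) + "]"


def nhx_annotation(node: Node) -> str:
    """NHX-style fragment ``[&&NHX:k=v:...]`` for a node.

    NHX has no list syntax and uses ``:``/``=`` as structure, so values
    containing those characters (or list values) are unrepresentable and
    raise ``ValueError``.
    """
    ann = node._annotation
    if not ann:
        return ""
    parts = []
    for key, value in ann.items():
        if isinstance(value, (list, tuple)):
            raise ValueError(f"NHX cannot represent list value for key {key!r}")
        if isinstance(value, bool):
            raise ValueError(f"NHX cannot represent boolean value for key {key!r}")
        text = _format_number(value) if isinstance(value, (int, float)) else str(value)
        bad = set(":=[],") & set(text) or set(":=[],") & set(key)
        if bad:
            raise ValueError(
                f"NHX cannot represent {key!r}={value!r}: "
                f"contains {''.join(sorted(bad))!r}"
            )
        parts.append(f"{key}={text}")
    return "[&&NHX:" + ":".join(parts) + "]"


def _node_suffix(node: Node, annotator: Optional[Annotator]) -> str:
    """Label + hybrid tag + annotations + branch length for one node."""
    out = []
    if node.label is not None:
        out.append(_format_label(node.label))
    if node.is_hybrid:
        out.append(f"#{node.hybrid_id}")
    fragment = annotator(node) if annotator is not None else ""
    nhx = fragment.startswith("[&&NHX")
    if fragment and not nhx:
        out.append(fragment)
    if node.branch_length is not None:
        out.append(":" + _format_number(node.branch_length))
    if fragment and nhx:
        out.append(fragment)
    return "".join(out)


def write_newick(tree: Tree, annotator: Optional[Annotator] = None) -> str:
    """Write a tree as a single ``;``-terminated Newick statement."""
    parts: list[str] = []
    # Work stack of ready-made text or nodes still to expand.
    stack: list[object] = [tree.root]
    while stack:
        item = stack.pop()
        if isinstance(item, str):
            parts.append(item)
            continue
        node = item  # type: ignore[assignment]
        if node.children:
            work: list[object] = ["("]
            for i, child in enumerate(node.children):
                if i:
                    work.append(",")
                work.append(child)
            work.append(")")
            work.append(_node_suffix(node, annotator))
            stack.extend(reversed(work))
        else:
            parts.append(_node_suffix(node, annotator))
    parts.append(";")
    return "".join(parts)


def write_nexus(tree: Tree, annotator: Optional[Annotator] = None) -> str:
    """Write one tree as a minimal Nexus document with a TREES block.

    Labels are written inline (no TRANSLATE block); readers accept both.
    """
    return write_nexus_document([tree], annotator)


def write_nexus_document(
    trees: Iterable[Tree], annotator: Optional[Annotator] = None
) -> str:
    """Nexus document holding any number of tree statements."""
    lines = ["#NEXUS", "begin trees;"]
    for i, tree in enumerate(trees, start=1):
        lines.append(f"tree TREE{i} = [&R] {write_newick(tree, annotator)}")
    lines.append("end;")
    return "\n".join(lines) + "\n"
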