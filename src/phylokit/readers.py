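"""Readers for the five supported tree formats.

The Newick reader is the workhorse: an *iterative*, explicit-stack parser
(no recursion), so pectinate trees with 10^5–10^6 tips parse without
recursion-depth failures.  It understands:

* multifurcations (any node arity);
* undefined branch lengths (simply no ``:len`` token);
* quoted labels (``'...'`` with ``''`` escaping) — underscores in
  unquoted labels are kept verbatim, *not* converted to spaces;
* BEAST-style annotations ``[&k=v,k2={a,b},...]``, accepted both before
  and after the ``:length`` token and merged into one annotation map;
* NHX annotations ``[&&NHX:k=v:...]``;
* plain square-bracket comments (no leading ``&``), which are discarded;
* extended-Newick hybrid tags: a label suffix ``#H1`` marks the node as
  hybrid with ``hybrid_id='H1'``; records sharing a hybrid id denote the
  same network node.

Nexus reading covers the TREES block with an optional TRANSLATE map;
PhyloXML and NeXML use the standard library XML parser; PhyJSON is a
minimal nested-object JSON convention documented in the methods note.
All readers take whole documents as text; the CLI handles files.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
import xml.etree.ElementTree as ET
from typing import Any, Optional

from .tree import Node, Tree

logger = logging.getLogger(__name__)

SCHEMAS = ("newick", "nexus", "phyloxml", "nexml", "phyjson")


class ParseError(ValueError):
    """Malformed input; carries the character offset where parsing failed."""

    def __init__(self, message: str, offset: Optional[int] = None) -> None:
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)


# ---------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------

# One master token pattern.  WORD covers unquoted labels, branch lengths
# and hybrid tags; it excludes whitespace, structural punctuation, braces,
# '=' and quote characters.  BRACKET swallows a whole [...] block,
# tolerating ] inside quoted annotation values.
_TOKEN = re.compile(
    r"""(?P<WS>\s+)
      | (?P<LP>\() | (?P<RP>\)) | (?P<COMMA>,) | (?P<COLON>:) | (?P<SEMI>;)
      | (?P<QUOTED>'(?:[^']|'')*')
      | (?P<BRACKET>\[(?:[^\]'"]|'[^']*'|"[^"]*")*\])
      | (?P<WORD>[^\s()\[\]{}:;,='"]+)
    """,
    re.VERBOSE,
)

_NUMBER = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?$")


def _unquote(token: str) -> str:
    return token[1:-1].replace("''", "'")


def _parse_scalar(token: str) -> Any:
    token = token.strip()
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1]
    if _NUMBER.match(token):
        return float(token)
    return token


def _split_top(text: str, sep: str) -> list[str]:
    """Split on ``sep`` outside braces and quotes."""
    out, buf, depth, quote = [], [], 0, ""
    for ch in text:
        if quote:
            buf.append(ch)
            if ch == quote:
                quote = ""
            continue
        if ch in "'\"":
            quote = ch
        elif ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
        elif ch == sep and depth == 0:
            out.append("".join(buf))
            buf = []
            continue
        buf.append(ch)
    out.append("".join(buf))
    return out


def _parse_beast_annotation(body: str, target: dict[str, Any], offset: int) -> None:
    """Parse the body of a ``[&...]`` block (leading ``&`` removed)."""
    for piece in _split_top(body, ","):
        piece = piece.strip()
        if not piece:
            continue
        key, eq, value = piece.partition("=")
        key = key.strip()
        if len(key) >= 2 and key[0] == key[-1] and key[0] in "'\"":
            key = key[1:-1]
        if not key:
            raise ParseError("annotation with empty key", offset)
        if not eq:
            target[key] = ""
            continue
        value = value.strip()
        if value.startswith("{"):
            if not value.endswith("}"):
                raise ParseError("unclosed '{' in annotation value", offset)
            inner = value[1:-1].strip()
            target[key] = (
                [_parse_scalar(v) for v in _split_top(inner, ",")] if inner else []
            )
        else:
            target[key] = _parse_scalar(value)


def _parse_nhx_annotation(body: str, target: dict[str, Any], offset: int) -> None:
    """Parse the body of a ``[&&NHX:...]`` block (``&&NHX`` removed)."""
    for piece in _split_top(body, ":"):
        piece = piece.strip()
        if not piece:
            continue
        key, eq, value = piece.partition("=")
        if not eq:
            raise ParseError(f"NHX entry {piece!r} lacks '='", offset)
        target[key.strip()] = _parse_scalar(value)


def _apply_bracket(token: str, node: Node, offset: int) -> bool:
    """Route a ``[...]`` token; returns True if it annotated the node."""
    body = token[1:-1]
    if body.startswith("&&NHX"):
        _parse_nhx_annotation(body[5:], node.annotation, offset)
        return True
    if body.startswith("&"):
        _parse_beast_annotation(body[1:], node.annotation, offset)
        return True
    return False  # plain comment: discarded


def _set_label(node: Node, text: str, offset: int, quoted: bool = False) -> None:
    if quoted:
        # quoted labels are verbatim: no hybrid-tag interpretation
        if node.label is not None:
            raise ParseError(f"unexpected second label {text!r}", offset)
        node.label = text
        return
    if node.label is not None and text.startswith("#") and not node.is_hybrid:
        # Hybrid tag following a (possibly quoted) label.
        node.is_hybrid = True
        node.hybrid_id = text[1:]
        if not node.hybrid_id:
            raise ParseError("empty hybrid identifier after '#'", offset)
        return
    if node.label is not None or node.is_hybrid:
        raise ParseError(f"unexpected second label {text!r}", offset)
    if "#" in text:
        name, _, tag = text.partition("#")
        if not tag:
            raise ParseError("empty hybrid identifier after '#'", offset)
        node.label = name or None
        node.is_hybrid = True
        node.hybrid_id = tag
    else:
        node.label = text


def read_newick(text: str) -> Tree:
    """Parse exactly one ``;``-terminated Newick statement into a Tree.

    Iterative explicit-stack parser; see the module docstring for the
    dialect.  Raises :class:`ParseError` with a character offset on
    malformed input.
    """
    root = Node()
    cur = root
    stack: list[Node] = []
    has_content = True  # the bare statement ';' is a valid single-node tree
    expect_length = False
    done = False
    pos, n = 0, len(text)

    while pos < n:
        m = _TOKEN.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        start = pos
        pos = m.end()
        if kind == "WS":
            continue
        if done:
            raise ParseError("trailing content after ';'", start)
        if expect_length and kind != "WORD":
            raise ParseError("expected a branch length after ':'", start)

        if kind == "LP":
            if cur.children or cur.label is not None or cur.branch_length is not None:
                raise ParseError("unexpected '('", start)
            child = Node()
            child.parent = cur
            cur.children.append(child)
            stack.append(cur)
            cur = child
            has_content = False
        elif kind == "COMMA":
            if not stack:
                raise ParseError("',' outside parentheses", start)
            if not has_content:
                raise ParseError("empty node before ','", start)
            parent = stack[-1]
            cur = Node()
            cur.parent = parent
            parent.children.append(cur)
            has_content = False
        elif kind == "RP":
            if not stack:
                raise ParseError("unbalanced ')'", start)
            if not has_content:
                raise ParseError("dangling comma before ')'", start)
            cur = stack.pop()
            has_content = True
        elif kind == "COLON":
            expect_length = True
            has_content = True
        elif kind == "WORD":
            if expect_length:
                if not _NUMBER.match(m.group()):
                    raise ParseError(f"invalid branch length {m.group()!r}", start)
                value = float(m.group())
                if value < 0:
                    warnings.warn(
                        f"negative branch length {value} at character {start}",
                        stacklevel=2,
                    )
                cur.branch_length = value
                expect_length = False
            else:
                if cur.branch_length is not None:
                    raise ParseError(
                        f"label {m.group()!r} after branch length", start
                    )
                _set_label(cur, m.group(), start)
            has_content = True
        elif kind == "QUOTED":
            if cur.branch_length is not None:
                raise ParseError("quoted label after branch length", start)
            _set_label(cur, _unquote(m.group()), start, quoted=True)
            has_content = True
        elif kind == "BRACKET":
            if _apply_bracket(m.group(), cur, start):
                has_content = True
        elif kind == "SEMI":
            if stack:
                raise ParseError("unbalanced '(': statement ended early", start)
            done = True

    if not done:
        raise ParseError("missing ';' terminator", n)
    return Tree(root)


def read_trees_from_newick(text: str) -> list[Tree]:
    """Parse newline-separated Newick statements; blank lines are skipped."""
    trees: list[Tree] = []
    for lineno, line in enumerate(text.split("\n"), start=1):
        if not line.strip():
            continue
        try:
            trees.append(read_newick(line))
        except ParseError as exc:
            raise ParseError(f"line {lineno}: {exc.args[0]}") from exc
    return trees


# ---------------------------------------------------------------------
# Nexus
# ---------------------------------------------------------------------


def _nexus_statements(text: str) -> list[str]:
    """Split a Nexus document into ``;``-terminated statements.

    Semicolons inside single quotes or square brackets do not terminate a
    statement; brackets are retained (tree statements carry annotations).
    """
    statements, buf = [], []
    depth, quoted = 0, False
    for ch in text:
        if quoted:
            buf.append(ch)
            if ch == "'":
                quoted = False
            continue
        if ch == "'":
            quoted = True
        elif ch == "[":
            depth += 1
        elif ch == "]":
            depth = max(0, depth - 1)
        elif ch == ";" and depth == 0:
            statements.append("".join(buf).strip())
            buf = []
            continue
        buf.append(ch)
    tail = "".join(buf).strip()
    if tail:
        statements.append(tail)
    return statements


_TRANSLATE_TOKEN = re.compile(r"\s*('(?:[^']|'')*'|[^\s,]+)")


def _parse_translate(body: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for entry in _split_top(body, ","):
        entry = entry.strip()
        if not entry:
            continue
        m = _TRANSLATE_TOKEN.match(entry)
        if m is None:
            raise ParseError(f"malformed TRANSLATE entry {entry!r}")
        token = m.group(1)
        name = entry[m.end():].strip()
        if not name:
            raise ParseError(f"TRANSLATE entry {entry!r} lacks a taxon name")
        if name.startswith("'") and name.endswith("'"):
            name = _unquote(name)
        mapping[token] = name
    return mapping


def _strip_leading_comments(text: str) -> str:
    """Drop leading ``[...]`` blocks (e.g. ``[&R]``/``[&U]`` rooting flags)."""
    text = text.lstrip()
    while text.startswith("["):
        end = text.find("]")
        if end < 0:
            raise ParseError("unterminated '[' in tree statement")
        text = text[end + 1 :].lstrip()
    return text


def read_nexus(text: str) -> list[Tree]:
    """Parse the TREES block of a Nexus document into a list of Trees.

    Keywords are case-insensitive.  An optional TRANSLATE statement maps
    tokens to taxon labels; a tree statement whose leaf label is a bare
    integer not covered by the map is an error.  Rooting comments such as
    ``[&R]`` are tolerated and ignored.
    """
    if not text.lstrip().lower().startswith("#nexus"):
        raise ParseError("missing #NEXUS header")
    body = text.lstrip()[len("#nexus") :]

    trees: list[Tree] = []
    translate: dict[str, str] = {}
    in_trees = False
    seen_trees_block = False

    for stmt in _nexus_statements(body):
        words = stmt.split(None, 1)
        if not words:
            continue
        keyword = words[0].lower()
        if keyword == "begin":
            block = words[1].strip().lower() if len(words) > 1 else ""
            in_trees = block == "trees"
            seen_trees_block = seen_trees_block or in_trees
        elif keyword in ("end", "endblock"):
            in_trees = False
        elif in_trees and keyword == "translate":
            translate = _parse_translate(words[1] if len(words) > 1 else "")
        elif in_trees and keyword == "tree":
            rest = words[1] if len(words) > 1 else ""
            _, eq, newick_part = rest.partition("=")
            if not eq:
                raise ParseError(f"tree statement without '=': {stmt!r}")
            newick_part = _strip_leading_comments(newick_part)
            if not newick_part.endswith(";"):
                newick_part += ";"
            tree = read_newick(newick_part)
            if translate:
                _apply_translate(tree, translate)
            trees.append(tree)

    if not seen_trees_block:
        raise ParseError("no TREES block found")
    return trees


def _apply_translate(tree: Tree, mapping: dict[str, str]) -> None:
    for node in tree.node_list:
        if node.label is None:
            continue
        if node.label in mapping:
            node.label = mapping[node.label]
        elif node.is_leaf() and node.label.isdigit():
            raise ParseError(
                f"tree references token {node.label!r} not defined in TRANSLATE"
            )


# ---------------------------------------------------------------------
# PhyloXML
# ---------------------------------------------------------------------


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _warn_unsupported(seen: set[str], tag: str, fmt: str) -> None:
    if tag not in seen:
        seen.add(tag)
        logger.warning("ignoring unsupported %s element <%s>", fmt, tag)


def read_phyloxml(text: str) -> list[Tree]:
    """Parse PhyloXML ``<phylogeny>`` elements into Trees.

    Supported per clade: ``name``, ``branch_length`` (element or
    attribute), ``confidence`` (stored as annotation) and nested
    ``clade`` children.  Other elements are ignored with a logged
    warning, never a crash.
    """
    try:
        doc = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"malformed PhyloXML: {exc}") from exc

    unsupported: set[str] = set()
    trees: list[Tree] = []
    for phylogeny in doc.iter():
        if _localname(phylogeny.tag) != "phylogeny":
            continue
        top = [el for el in phylogeny if _localname(el.tag) == "clade"]
        if not top:
            raise ParseError("phylogeny without a clade element")
        root = Node()
        stack = [(top[0], root)]
        while stack:
            clade_el, node = stack.pop()
            bl_attr = clade_el.get("branch_length")
            if bl_attr is not None:
                node.branch_length = float(bl_attr)
            for el in clade_el:
                tag = _localname(el.tag)
                if tag == "clade":
                    child = Node()
                    child.parent = node
                    node.children.append(child)
                    stack.append((el, child))
                elif tag == "name":
                    node.label = (el.text or "").strip() or None
                elif tag == "branch_length":
                    node.branch_length = float((el.text or "").strip())
                elif tag == "confidence":
                    node.annotation["confidence"] = _parse_scalar(
                        (el.text or "").strip()
                    )
                elif tag == "taxon" or tag == "taxonomy":
                    for sub in el:
                        if _localname(sub.tag) == "scientific_name":
                            node.label = (sub.text or "").strip() or None
                else:
                    _warn_unsupported(unsupported, tag, "PhyloXML")
        trees.append(Tree(root))
    if not trees:
        raise ParseError("no phylogeny element found")
    return trees


# ---------------------------------------------------------------------
# NeXML
# ---------------------------------------------------------------------


def read_nexml(text: str) -> list[Tree]:
    """Parse NeXML ``<tree>`` elements (node + edge lists) into Trees."""
    try:
        doc = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ParseError(f"malformed NeXML: {exc}") from exc

    otu_labels: dict[str, str] = {}
    for el in doc.iter():
        if _localname(el.tag) == "otu":
            ident = el.get("id")
            if ident:
                otu_labels[ident] = el.get("label") or ident

    trees: list[Tree] = []
    for tree_el in doc.iter():
        if _localname(tree_el.tag) != "tree":
            continue
        nodes: dict[str, Node] = {}
        flagged_root: Optional[Node] = None
        for el in tree_el:
            if _localname(el.tag) != "node":
                continue
            ident = el.get("id")
            if ident is None:
                raise ParseError("NeXML node without id")
            label = el.get("label")
            otu = el.get("otu")
            if label is None and otu is not None:
                label = otu_labels.get(otu, otu)
            node = Node(label)
            nodes[ident] = node
            if (el.get("root") or "").lower() == "true":
                flagged_root = node
        for el in tree_el:
            if _localname(el.tag) != "edge":
                continue
            source, target = el.get("source"), el.get("target")
            if source not in nodes or target not in nodes:
                raise ParseError(
                    f"NeXML edge references unknown node ({source!r} -> {target!r})"
                )
            child = nodes[target]
            if child.parent is not None:
                raise ParseError(f"NeXML node {target!r} has two incoming edges")
            length = el.get("length")
            if length is not None:
                child.branch_length = float(length)
            nodes[source].children.append(child)
            child.parent = nodes[source]
        root = flagged_root
        if root is None:
            parentless = [n for n in nodes.values() if n.parent is None]
            if len(parentless) != 1:
                raise ParseError(
                    f"cannot identify the NeXML root ({len(parentless)} candidates)"
                )
            root = parentless[0]
        trees.append(Tree(root))
    if not trees:
        raise ParseError("no tree element found")
    return trees


# ---------------------------------------------------------------------
# PhyJSON
# ---------------------------------------------------------------------


def _node_from_obj(obj: dict) -> Node:
    if not isinstance(obj, dict):
        raise ParseError(f"PhyJSON node must be an object, got {type(obj).__name__}")
    root = Node(obj.get("name"), obj.get("length"))
    stack = [(obj, root)]
    while stack:
        spec, node = stack.pop()
        ann = spec.get("annotations")
        if ann:
            node.annotation.update(ann)
        hybrid = spec.get("hybrid")
        if hybrid is not None:
            node.is_hybrid = True
            node.hybrid_id = str(hybrid)
        for child_spec in spec.get("children", []):
            if not isinstance(child_spec, dict):
                raise ParseError("PhyJSON child must be an object")
            child = Node(child_spec.get("name"), child_spec.get("length"))
            child.parent = node
            node.children.append(child)
            stack.append((child_spec, child))
    return root


def read_phyjson(text: str) -> list[Tree]:
    """Parse a PhyJSON document (this package's minimal convention).

    Accepted top-level forms: ``{"trees": [node, ...]}``, a bare list of
    node objects, or a single node object.  A node object has optional
    keys ``name``, ``length``, ``children``, ``annotations`` and
    ``hybrid`` (the hybrid identifier).
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed PhyJSON: {exc}", exc.pos) from exc
    if isinstance(doc, dict) and "trees" in doc:
        tree_objs = doc["trees"]
    elif isinstance(doc, list):
        tree_objs = doc
    elif isinstance(doc, dict):
        tree_objs = [doc]
    else:
        raise ParseError("PhyJSON document must be an object or a list")
    if not isinstance(tree_objs, list):
        raise ParseError("PhyJSON 'trees' must be a list")
    return [Tree(_node_from_obj(obj)) for obj in tree_objs]


# ---------------------------------------------------------------------
# Generic dispatch
# ---------------------------------------------------------------------

_READERS = {
    "newick": read_trees_from_newick,
    "nexus": read_nexus,
    "phyloxml": read_phyloxml,
    "nexml": read_nexml,
    "phyjson": read_phyjson,
}


def read(text: str, schema: str) -> list[Tree]:
    """Read trees from ``text`` in the named schema.

    Always returns a list, even for single-tree input.  ``schema`` must
    be one of ``newick``, ``nexus``, ``phyloxml``, ``nexml``, ``phyjson``.
    """
    try:
        reader = _READERS[schema.lower()]
    except KeyError:
        raise ValueError(
            f"unknown schema {schema!r}; expected one of {', '.join(SCHEMAS)}"
        ) from None
    return reader(text)
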