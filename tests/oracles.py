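"""Independent test oracles.

Everything here is deliberately simple and written along a different
mechanical path from the package: a *recursive-descent* Newick parser
(the package parser is an explicit-stack machine), naive full-recursion
imbalance indices, an ancestor-set MRCA, and brute-force path lengths.
They exist to cross-check the implementation, never to power it.
"""

from __future__ import annotations

import random

from phylokit import Node, Tree


# ---------------------------------------------------------------------
# Recursive-descent Newick parser -> nested dicts
# ---------------------------------------------------------------------


def _scalar(tok: str):
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == tok[-1] and tok[0] in "'\"":
        return tok[1:-1]
    try:
        return float(tok)
    except ValueError:
        return tok


def _split_outside(text: str, sep: str) -> list[str]:
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


def _annotation_dict(body: str) -> dict:
    ann: dict = {}
    if body.startswith("&&NHX"):
        for piece in _split_outside(body[5:], ":"):
            piece = piece.strip()
            if piece:
                k, _, v = piece.partition("=")
                ann[k.strip()] = _scalar(v)
        return ann
    assert body.startswith("&")
    for piece in _split_outside(body[1:], ","):
        piece = piece.strip()
        if not piece:
            continue
        k, eq, v = piece.partition("=")
        k = k.strip()
        if len(k) >= 2 and k[0] == k[-1] and k[0] in "'\"":
            k = k[1:-1]
        if not eq:
            ann[k] = ""
            continue
        v = v.strip()
        if v.startswith("{"):
            inner = v[1:-1].strip()
            ann[k] = [_scalar(x) for x in _split_outside(inner, ",")] if inner else []
        else:
            ann[k] = _scalar(v)
    return ann


def oracle_parse_newick(text: str) -> dict:
    """Recursive-descent parse to nested dicts.

    Node dict keys: label, length, children, annotation, hybrid.
    """
    s = text.strip()
    assert s.endswith(";"), "oracle expects a ';'-terminated statement"
    s = s[:-1]
    pos = 0

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def read_bracket() -> str:
        nonlocal pos
        assert s[pos] == "["
        start = pos
        pos += 1
        quote = ""
        while pos < len(s):
            ch = s[pos]
            if quote:
                if ch == quote:
                    quote = ""
            elif ch in "'\"":
                quote = ch
            elif ch == "]":
                pos += 1
                return s[start + 1 : pos - 1]
            pos += 1
        raise AssertionError("unterminated bracket in oracle input")

    def read_word() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "()[]{}:;,='\"" and not s[pos].isspace():
            pos += 1
        return s[start:pos]

    def read_quoted() -> str:
        nonlocal pos
        assert s[pos] == "'"
        pos += 1
        out = []
        while True:
            ch = s[pos]
            if ch == "'":
                if pos + 1 < len(s) and s[pos + 1] == "'":
                    out.append("'")
                    pos += 2
                    continue
                pos += 1
                return "".join(out)
            out.append(ch)
            pos += 1

    def parse_node() -> dict:
        nonlocal pos
        node = {
            "label": None,
            "length": None,
            "children": [],
            "annotation": {},
            "hybrid": None,
        }
        skip_ws()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node["children"].append(parse_node())
                skip_ws()
                if s[pos] == ",":
                    pos += 1
                    continue
                assert s[pos] == ")"
                pos += 1
                break
        # suffix: label / hybrid tag / annotations / :length / annotations
        while True:
            skip_ws()
            if pos >= len(s) or s[pos] in ",)":
                return node
            ch = s[pos]
            if ch == "'":
                node["label"] = read_quoted()
            elif ch == "[":
                body = read_bracket()
                if body.startswith("&"):
                    node["annotation"].update(_annotation_dict(body))
            elif ch == ":":
                pos += 1
                skip_ws()
                node["length"] = float(read_word())
            else:
                word = read_word()
                assert word, f"oracle stuck at {s[pos:pos+10]!r}"
                if word.startswith("#") and node["label"] is not None:
                    node["hybrid"] = word[1:]
                elif "#" in word:
                    name, _, tag = word.partition("#")
                    node["label"] = name or None
                    node["hybrid"] = tag
                else:
                    node["label"] = word

    root = parse_node()
    skip_ws()
    assert pos == len(s), f"oracle left trailing input {s[pos:]!r}"
    return root


def tree_matches_oracle(tree: Tree, oracle: dict) -> bool:
    """Compare a package Tree against an oracle dict, field by field."""
    stack = [(tree.root, oracle)]
    while stack:
        node, ref = stack.pop()
        if node.label != ref["label"]:
            return False
        if (node.branch_length is None) != (ref["length"] is None):
            return False
        if node.branch_length is not None and node.branch_length != ref["length"]:
            return False
        if (node.hybrid_id or None) != ref["hybrid"]:
            return False
        if (node._annotation or {}) != ref["annotation"]:
            return False
        if len(node.children) != len(ref["children"]):
            return False
        stack.extend(zip(node.children, ref["children"]))
    return True


# ---------------------------------------------------------------------
# Naive recursive statistics
# ---------------------------------------------------------------------


def naive_leaf_count(node: Node) -> int:
    if not node.children:
        return 1
    return sum(naive_leaf_count(c) for c in node.children)


def naive_sackin(node: Node, depth: int = 0) -> int:
    if not node.children:
        return depth
    return sum(naive_sackin(c, depth + 1) for c in node.children)


def naive_colless(node: Node) -> int:
    if not node.children:
        return 0
    assert len(node.children) == 2, "naive Colless expects a binary tree"
    left, right = node.children
    return (
        abs(naive_leaf_count(left) - naive_leaf_count(right))
        + naive_colless(left)
        + naive_colless(right)
    )


# ---------------------------------------------------------------------
# MRCA and path lengths by brute force
# ---------------------------------------------------------------------


def brute_mrca(nodes: list[Node]) -> Node:
    """Intersect ancestor-or-self sets; return the deepest member."""
    common: set[int] | None = None
    by_id: dict[int, Node] = {}
    for node in nodes:
        chain = [node] + node.get_ancestors()
        ids = {id(n) for n in chain}
        by_id.update({id(n): n for n in chain})
        common = ids if common is None else (common & ids)
    assert common
    return max(
        (by_id[i] for i in common), key=lambda n: len(n.get_ancestors())
    )


def brute_leaf_path_lengths(tree: Tree) -> dict[tuple[str, str], float]:
    """All leaf-pair path lengths via root distances and brute-force LCAs."""
    root_dist: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        root_dist[id(node)] = root_dist[id(node.parent)] + (node.branch_length or 0.0)
    leaves = tree.leaf_list
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            lca = brute_mrca([a, b])
            key = tuple(sorted((a.label or "", b.label or "")))
            out[key] = root_dist[id(a)] + root_dist[id(b)] - 2 * root_dist[id(lca)]
    return out


# ---------------------------------------------------------------------
# Messy random trees for round-trip / parser-equivalence testing
# ---------------------------------------------------------------------


def random_messy_tree(
    rng: random.Random,
    max_extra_nodes: int = 40,
    dialect: str = "beast",
) -> Tree:
    """Random tree mixing multifurcations, absent lengths, quoted labels
    and dialect-appropriate annotations (<= 64 leaves by construction)."""
    root = Node()
    nodes = [root]
    for _ in range(rng.randint(1, max_extra_nodes)):
        parent = rng.choice(nodes)
        child = Node()
        parent.add_child(child)
        nodes.append(child)
    for i, node in enumerate(nodes):
        if not node.children or rng.random() < 0.3:
            style = rng.random()
            if style < 0.5:
                node.label = f"t{i}"
            elif style < 0.65:
                node.label = f"sp {i} (x:y)"  # forces quoting
            elif style < 0.75:
                node.label = f"it'{i}"  # embedded quote
            elif style < 0.85:
                node.label = f"tax_{i}_a"
            else:
                node.label = f"{i}e5"  # numeric-looking label
        if node.parent is not None and rng.random() < 0.8:
            node.branch_length = round(rng.uniform(0.0, 5.0), 6)
        if rng.random() < 0.3:
            if dialect == "nhx":
                node.annotation = {
                    "S": f"sp{i}",
                    "B": float(round(rng.uniform(0, 100), 3)),
                }
            else:
                node.annotation = {
                    "rate": round(rng.random(), 6),
                    "loc": f"deme {i}",
                    "hpd": [round(rng.random(), 4), round(1 + rng.random(), 4)],
                }
    return Tree(root)
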