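"""Parsing of all five formats, annotation dialects and error handling."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from phylokit import (
    ParseError,
    read,
    read_newick,
    read_nexml,
    read_nexus,
    read_phyjson,
    read_phyloxml,
    read_trees_from_newick,
    trees_equal,
    write_newick,
)
from conftest import WORKED_NEWICK
from oracles import random_messy_tree

# ---------------------------------------------------------------- Newick


def test_worked_example_structure(worked_tree):
    assert [n.label for n in worked_tree.leaf_list] == ["a", "b", "c", "d"]
    assert sum(1 for n in worked_tree.node_list if n.children) == 3
    assert worked_tree.root.branch_length is None
    assert worked_tree.node_list[1].branch_length == 1.0


def test_bare_semicolon_is_single_root():
    tree = read_newick(";")
    assert len(tree.node_list) == 1
    assert tree.root.label is None
    assert tree.root.branch_length is None


def test_beast_annotation_on_leaf():
    tree = read_newick("(A[&rate=0.5]:1,B:2);")
    leaf_a = tree.leaf_list[0]
    assert leaf_a.label == "A"
    assert leaf_a.annotation == {"rate": 0.5}
    assert leaf_a.branch_length == 1.0


def test_beast_annotation_after_branch_length_merges():
    tree = read_newick("(A[&a=1]:1[&b={2,x}],B:2);")
    assert tree.leaf_list[0].annotation == {"a": 1.0, "b": [2.0, "x"]}


def test_nhx_annotation_block():
    tree = read_newick("((A:1,B:1):1[&&NHX:S=primate:D=N],C:2);")
    assert tree.node_list[1].annotation == {"S": "primate", "D": "N"}


def test_plain_comments_are_discarded():
    tree = read_newick("(A[this is a comment]:1,B:2);")
    assert tree.leaf_list[0]._annotation is None


def test_extended_newick_hybrid_records():
    tree = read_newick("((A,B)#H1:1,(#H1:0.5,C):1);")
    hybrids = [n for n in tree.node_list if n.is_hybrid]
    assert len(hybrids) == 2
    assert {n.hybrid_id for n in hybrids} == {"H1"}
    assert hybrids[0].children and not hybrids[1].children


def test_quoted_labels_and_underscores():
    tree = read_newick("('one two':1,under_score:2);")
    assert tree.leaf_list[0].label == "one two"
    # underscores stay verbatim, never become spaces
    assert tree.leaf_list[1].label == "under_score"


def test_quoted_label_with_escaped_quote():
    tree = read_newick("('it''s':1,B:1);")
    assert tree.leaf_list[0].label == "it's"


def test_negative_branch_length_warns_but_parses():
    with pytest.warns(UserWarning, match="negative branch length"):
        tree = read_newick("(A:-1e-8,B:2);")
    assert tree.leaf_list[0].branch_length == -1e-8


@pytest.mark.parametrize(
    "bad",
    [
        "((A,B);",          # unbalanced '('
        "(A,B));",          # unbalanced ')'
        "(A,);",            # dangling comma
        "(A,B)",            # missing ';'
        "(A:x,B);",         # malformed branch length
        "('A,B);",          # unterminated quote
        "(A,B); extra",     # trailing content
        "(A[&k=1,B);",      # unterminated annotation
    ],
)
def test_malformed_newick_raises_parse_error(bad):
    with pytest.raises(ParseError):
        read_newick(bad)


def test_parse_error_carries_offset():
    with pytest.raises(ParseError) as err:
        read_newick("(A,B));")
    assert err.value.offset == 5


def test_whitespace_between_tokens_is_ignored():
    spaced = "(( a :2 , b : 2 ) : 1 , ( c :1 , d : 1 ) : 4 ) ;"
    assert trees_equal(read_newick(spaced), read_newick(WORKED_NEWICK))


def test_whitespace_insensitivity_on_random_trees():
    from phylokit import beast_annotation

    rng = random.Random(42)
    for _ in range(25):
        tree = random_messy_tree(rng)
        text = write_newick(tree, beast_annotation)
        # insert whitespace at structural positions, outside quotes/brackets
        out, quoted, depth = [], False, 0
        for ch in text:
            if quoted:
                out.append(ch)
                quoted = ch != "'"
                continue
            if ch == "'":
                quoted = True
            elif ch == "[":
                depth += 1
            elif ch == "]":
                depth -= 1
            if ch in "(),;" and depth == 0 and not quoted:
                out.append(f" {ch}\n ")
            else:
                out.append(ch)
        assert trees_equal(read_newick("".join(out)), tree)


def test_deeply_nested_tree_parses_iteratively():
    n = 10_000
    text = "(" * n + "A" + ":1)" * n + ";"
    tree = read_newick(text)
    assert len(tree.node_list) == n + 1


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    label=st.text(
        alphabet=st.characters(codec="ascii", exclude_characters="\x00\r\n"),
        min_size=1,
        max_size=20,
    ),
    length=st.floats(min_value=0, max_value=1e6, allow_nan=False),
)
def test_any_label_and_length_round_trip(label, length):
    tree = read_newick(WORKED_NEWICK)
    tree.leaf_list[0].label = label
    tree.leaf_list[0].branch_length = length
    again = read_newick(write_newick(tree))
    assert again.leaf_list[0].label == label
    assert again.leaf_list[0].branch_length == length


# ------------------------------------------------------------ multi-tree


def test_two_line_newick_gives_two_trees():
    text = "((A:1,B:1):1,C:1);\n((A:1,B:1):1,C:1);"
    trees = read_trees_from_newick(text)
    assert len(trees) == 2
    assert all(len(t.leaf_list) == 3 for t in trees)


def test_empty_string_gives_empty_list():
    assert read_trees_from_newick("") == []


def test_multi_tree_error_reports_line_number():
    with pytest.raises(ParseError, match="line 2"):
        read_trees_from_newick("(A,B);\n(A,B));\n(C,D);")


def test_joined_generated_trees_count():
    from phylokit import generate_tree

    k = 7
    text = "\n".join(
        write_newick(generate_tree(n_tips=5, seed=s)) for s in range(k)
    )
    assert len(read_trees_from_newick(text)) == k


# ---------------------------------------------------------------- Nexus


def test_minimal_nexus_matches_newick(worked_tree):
    doc = f"#NEXUS\nbegin trees;\ntree one = {WORKED_NEWICK}\nend;\n"
    trees = read_nexus(doc)
    assert len(trees) == 1
    assert trees_equal(trees[0], worked_tree)


def test_nexus_translate_substitution():
    doc = (
        "#NEXUS\nBEGIN TREES;\n  TRANSLATE\n    1 Homo,\n    2 Pan;\n"
        "  TREE t1 = [&R] (1:1,2:1);\nEND;\n"
    )
    tree = read_nexus(doc)[0]
    assert [n.label for n in tree.leaf_list] == ["Homo", "Pan"]


def test_nexus_three_tree_statements():
    doc = (
        "#NEXUS\nbegin trees;\n"
        "tree a = (A,B);\ntree b = (A,(B,C));\ntree c = (B,A);\n"
        "end;\n"
    )
    assert len(read_nexus(doc)) == 3


def test_nexus_requires_header_and_trees_block():
    with pytest.raises(ParseError):
        read_nexus("(A,B);")
    with pytest.raises(ParseError, match="TREES"):
        read_nexus("#NEXUS\nbegin taxa;\nend;\n")


def test_nexus_undefined_translate_token():
    doc = (
        "#NEXUS\nbegin trees;\ntranslate 1 Homo;\ntree t = (1:1,2:1);\nend;\n"
    )
    with pytest.raises(ParseError, match="TRANSLATE"):
        read_nexus(doc)


# ------------------------------------------------------- PhyloXML / NeXML


PHYLOXML_WORKED = """<?xml version="1.0"?>
<phyloxml xmlns="http://www.phyloxml.org">
 <phylogeny rooted="true">
  <clade>
   <clade><branch_length>1</branch_length>
    <clade><name>a</name><branch_length>2</branch_length></clade>
    <clade><name>b</name><branch_length>2</branch_length></clade>
   </clade>
   <clade><branch_length>4</branch_length>
    <clade><name>c</name><branch_length>1</branch_length></clade>
    <clade><name>d</name><branch_length>1</branch_length></clade>
   </clade>
  </clade>
 </phylogeny>
</phyloxml>
"""


def test_phyloxml_matches_newick(worked_tree):
    trees = read_phyloxml(PHYLOXML_WORKED)
    assert len(trees) == 1
    assert trees_equal(trees[0], worked_tree)


def test_phyloxml_ignores_unknown_elements(caplog):
    doc = PHYLOXML_WORKED.replace(
        "<name>a</name>", "<name>a</name><mystery>7</mystery>"
    )
    import logging

    with caplog.at_level(logging.WARNING):
        trees = read_phyloxml(doc)
    assert trees_equal(trees[0], read_phyloxml(PHYLOXML_WORKED)[0])
    assert any("mystery" in r.message for r in caplog.records)


NEXML_MINIMAL = """<?xml version="1.0"?>
<nexml xmlns="http://www.nexml.org/2009">
 <otus id="taxa1">
  <otu id="o1" label="A"/><otu id="o2" label="B"/>
 </otus>
 <trees otus="taxa1" id="trees1">
  <tree id="tree1">
   <node id="n0" root="true"/>
   <node id="n1" otu="o1"/>
   <node id="n2" otu="o2"/>
   <edge source="n0" target="n1" length="1"/>
   <edge source="n0" target="n2" length="1"/>
  </tree>
 </trees>
</nexml>
"""


def test_nexml_minimal_two_leaf_tree():
    tree = read_nexml(NEXML_MINIMAL)[0]
    assert [n.label for n in tree.leaf_list] == ["A", "B"]
    assert [n.branch_length for n in tree.leaf_list] == [1.0, 1.0]


def test_nexml_unknown_edge_reference():
    with pytest.raises(ParseError, match="unknown node"):
        read_nexml(NEXML_MINIMAL.replace('target="n2"', 'target="n9"'))


# --------------------------------------------------------------- PhyJSON


PHYJSON_WORKED = """
{"trees": [
  {"children": [
    {"length": 1, "children": [
      {"name": "a", "length": 2}, {"name": "b", "length": 2}]},
    {"length": 4, "children": [
      {"name": "c", "length": 1}, {"name": "d", "length": 1}]}
  ]}
]}
"""


def test_phyjson_matches_newick(worked_tree):
    trees = read_phyjson(PHYJSON_WORKED)
    assert len(trees) == 1
    assert trees_equal(trees[0], worked_tree)


def test_phyjson_two_tree_document():
    doc = '{"trees": [{"name": "x"}, {"children": [{"name": "y"}, {"name": "z"}]}]}'
    assert len(read_phyjson(doc)) == 2


def test_phyjson_annotations_and_hybrids():
    doc = (
        '{"trees": [{"children": ['
        '{"name": "A", "length": 1, "annotations": {"rate": 0.5}},'
        '{"hybrid": "H1", "length": 0.25}]}]}'
    )
    tree = read_phyjson(doc)[0]
    assert tree.leaf_list[0].annotation == {"rate": 0.5}
    assert tree.leaf_list[1].is_hybrid and tree.leaf_list[1].hybrid_id == "H1"


# ------------------------------------------------------- generic dispatch


def test_read_always_returns_list(worked_tree):
    trees = read(WORKED_NEWICK, "newick")
    assert isinstance(trees, list) and len(trees) == 1
    assert trees_equal(trees[0], worked_tree)


def test_read_two_statement_newick():
    assert len(read("(A,B);\n(C,D);", "newick")) == 2


def test_read_wrong_schema_fails_loudly():
    with pytest.raises(ParseError):
        read(WORKED_NEWICK, "nexus")


def test_read_unknown_schema():
    with pytest.raises(ValueError, match="unknown schema"):
        read(WORKED_NEWICK, "fasta")


def test_cross_format_agreement(worked_tree):
    nexus_doc = f"#NEXUS\nbegin trees;\ntree t = {WORKED_NEWICK}\nend;\n"
    parsed = {
        "newick": read(WORKED_NEWICK, "newick")[0],
        "nexus": read(nexus_doc, "nexus")[0],
        "phyloxml": read(PHYLOXML_WORKED, "phyloxml")[0],
        "phyjson": read(PHYJSON_WORKED, "phyjson")[0],
    }
    for name, tree in parsed.items():
        assert trees_equal(tree, worked_tree), name
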