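# Methods

## Data model

A tree is a recursive arrangement of `Node` objects under a `Tree`
wrapper.  Each node stores the length of the branch *leading into* it
(`branch_length`, optional — `None` means undefined), an ordered child
list of any arity, an optional label, an annotation map, and an optional
hybrid tag.  `Tree.node_list` is the pre-order sequence (root first,
children left to right) and node ids are pre-order indices, reassigned
after every topology change; this makes `tree.node_list[k]` a stable,
documented way to address nodes.  Pre-order for `node_list` is this
package's documented convention.

Phylogenetic networks are held in extended-Newick style: a hybrid node
appears as several tree-shaped records sharing one `hybrid_id`, rather
than as a true DAG.  This keeps every traversal tree-shaped and matches
eNewick semantics; the cost is that network-aware algorithms must
reunify records themselves, and reroot/prune refuse to operate across a
hybrid attachment rather than silently break the network.

All traversals, the Newick parser and the writer are iterative with
explicit stacks.  This is not a style choice: a pectinate tree of 10⁵+
tips overflows the interpreter call stack under any recursive design,
and handling 10⁶-tip trees is a stated capability of the package.

## Newick dialect

* Unquoted labels exclude whitespace and `( ) [ ] { } : ; , = ' "`;
  quoted labels use `'...'` with `''` escaping.  Underscores are kept
  verbatim, *not* converted to spaces (a deliberate deviation from one
  Newick tradition, chosen for round-trip safety).
* `[&...]` blocks (BEAST/FigTree) are accepted both after the label and
  after the branch length; both merge into the same per-node annotation
  map.  Whether node- and branch-placed annotations should stay distinct
  is genuinely open; merging was chosen and is documented here.
  Values: unquoted numeric tokens parse as floats, quoted tokens as
  strings, `{a,b,...}` as ordered lists.
* `[&&NHX:...]` blocks parse into the same map.  Plain `[...]` comments
  (no leading `&`) are discarded.
* A label suffix `#H1` (label part optional) marks a hybrid record.
  Inside quotes, `#` is literal.
* Branch lengths accept decimal and scientific notation.  Negative
  lengths are tolerated with a warning (BEAST output contains tiny
  negative lengths in practice); generated trees always satisfy ≥ 0.
* Writing: branch lengths use the shortest round-tripping decimal
  representation; labels are quoted only when needed; undefined branch
  lengths produce no `:len` token; string annotation values are always
  double-quoted so numeric-looking strings survive a round trip;
  polytomies are written as-is.  BEAST fragments are emitted before the
  `:length` token, NHX fragments after it, matching the placement each
  tool family uses.
* Exact output strings are not a compatibility surface; fidelity is
  defined by reparse equality (topology, labels, lengths, annotations).

## Other formats

* **Nexus**: case-insensitive keywords; statements split on `;` outside
  quotes and brackets; TREES block with optional TRANSLATE map; rooting
  comments `[&R]`/`[&U]` tolerated and ignored.  A bare-integer leaf
  token not covered by a present TRANSLATE map is an error.  The writer
  emits labels inline and no TRANSLATE block.  Character/data blocks
  are out of scope.
* **PhyloXML / NeXML**: standard-library XML parsing, namespace-
  agnostic.  Supported content: nested clades with name/branch_length/
  confidence (PhyloXML) and node/edge lists with otu label resolution
  (NeXML).  Unsupported elements are skipped with a logged warning,
  never a crash.
* **PhyJSON**: no authoritative schema exists, so this package defines a
  minimal convention: a document is `{"trees": [node, ...]}`, a list of
  nodes, or a single node; a node object has optional `name`, `length`,
  `children`, `annotations`, `hybrid`.
* Only Newick and Nexus are written.  Multi-tree Newick output is the
  caller joining statements with `\n`; a `write_nexus_document` helper
  exists so the CLI can emit one TREES block for many trees.

## Manipulation semantics

* **reroot(tree, node, proportion=0.5)** splits the branch above
  `node`: the new root takes `node` (with `proportion ×` the old
  length) and the re-oriented remainder (with the complement) as its
  two children; edges between the old root and the attachment point are
  reversed with their lengths; an old root left unary is merged into
  its child (lengths summed, child's annotations win); the new root's
  own length is set to 0.0, so rerooted trees serialise with a trailing
  `:0.0`.  Branch-splitting (rather than re-hanging at the node) was an
  open design point; it matches midpoint-style usage and makes the
  proportion argument meaningful.  Conserved exactly: leaf set, total
  branch length (the root's own length excluded), all leaf-to-leaf path
  lengths.
* **ladderise** sorts children by descendant-leaf count ascending, ties
  broken by the smallest descendant leaf label — the tie-break makes
  the operation idempotent and deterministic.
* **get_clade** returns a deep copy whose root *retains* its incoming
  branch length.  Copying (not structure-sharing) makes the extraction
  semantics unambiguous and mutation-safe.  The retained branch is what
  makes the IE-ratio clade values come out as 0.25 / 2.00 on the worked
  example.
* **prune** detaches a clade (incoming length retained) and suppresses
  a parent left unary; **graft** attaches a subtree under a target with
  a given non-negative length.  `remove_child` itself never suppresses
  the resulting unary node — silent suppression would break annotation
  round trips — a separate `suppress_unary` utility does it on request.

## Statistics

* **IE ratio**: internal-sum / external-sum over *defined* branch
  lengths; a non-leaf root's defined length counts as internal; zero
  external sum is an error.  `annotate_ie_ratios` stores the value on
  each internal node under `ieRatio` as a two-decimal,
  half-away-from-zero string (decimal arithmetic, mirroring JavaScript
  `toFixed(2)`), computed per clade via `get_clade`.
* **Sackin**: Σ leaf depths (root depth 0).  **Colless**: Σ |left −
  right| leaf counts; bifurcating trees only, errors on polytomies
  (polytomies are never silently resolved anywhere in the package).
* **Gamma** (Pybus–Harvey): computed from sorted internal-node heights;
  requires ≥ 3 leaves, binary topology, ultrametricity to 1e-6 relative
  tolerance (tip-height spread / max height).  Scale-invariant by
  construction; ≈ N(0,1) under pure birth.  Hand-checked on the n = 3
  case `((A:1,B:1):1,C:2);` (γ = −0.5/(5·√(1/12)) ≈ −0.346) and
  cross-checked against an independent implementation in the tests.
* **Root-to-tip regression**: OLS (numpy) of root-to-tip distance on
  caller-supplied tip times; requires ≥ 2 distinct times.  No date
  parsing from labels and no local-clock search — callers own those.
  A single-node tree has root-to-tip distance 0 by convention.

## Synthetic trees

Randomness uses SplitMix64, fully specified in `phylokit/_rng.py`, so
seeded output is bit-identical across platforms (the platform RNG makes
no such guarantee).  `generate_tree` produces binary trees with leaves
`t1..tN` and exponential branch lengths, default mean 1.0 (a neutral
unit scale; statistics under test are either scale-invariant or scale
linearly):

* `yule` — repeated uniform joins of subtree roots; used for random
  topologies and the large-scale benchmarks (10¹–10⁶ tips).
* `caterpillar` — fully pectinate; the deep-nesting stress case.
* `balanced` — perfect binary tree (power-of-two tip counts).

`generate_ultrametric_tree` simulates a pure-birth process forward in
time (interval with k lineages ~ Exponential(k·λ), uniform choice of
splitting lineage), giving exactly ultrametric trees with the correct
Yule internode distribution for the Gamma sanity checks.
`generate_benchmark_suite` writes one seeded Newick file per requested
size.  Hybrid injection duplicates random internal nodes as `#H<k>`
reference records — a parser fixture, with no biological model claimed.

What the generators do *not* emulate: rate heterogeneity, sampled
(heterochronous) tips, polytomies or missing lengths (the messy mixes
used in round-trip tests are built separately in the test suite), or
realistic taxon names.  Passing tests therefore demonstrate structural
and numerical correctness of the operations, not robustness to every
real-world file quirk.

## Numerical choices and degenerate inputs

* Branch-length equality in round trips is exact (shortest-repr
  serialisation); conservation laws under rerooting are checked to 1e-9
  relative tolerance (float summation order changes).
* Ladderise ties, annotation key order (insertion order), and pre-order
  ids are all deterministic.
* The bare statement `;` is a valid single-node tree; `(A,)` -style
  dangling commas are parse errors with character offsets.
* Problem sizes used in the shipped tests: 10⁶-tip Yule and 10⁵-tip
  pectinate trees for the scale checks; 1000 trees (≤ 64 leaves) for
  round-trip and oracle-equivalence properties; 500 instances for
  rerooting conservation; 500 pure-birth replicates at n = 50 for the
  Gamma mean check.

## Known limitations

* Networks are duplicate-record representations; no network-aware
  rerooting, pruning or statistics.
* No URL fetching, no streaming parsers, no Nexus character blocks, no
  PhyloXML/NeXML/PhyJSON writing, no visualisation.
* Root-to-tip regression reports no confidence intervals.
* The MRCA label lookup uses the first node carrying a label when
  labels are duplicated.
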