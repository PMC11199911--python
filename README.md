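# phylokit

A utility library (and small CLI) for **reading, writing, manipulating and
summarising rooted phylogenetic trees and networks**, aimed at anyone who
needs tree plumbing — epidemiologists post-processing BEAST posteriors,
developers of tree-visualisation tools, or methods people who want fast,
dependable parse/manipulate/serialise primitives without pulling in a
full phylogenetics framework.

## What it does

* **Parse five formats**: Newick (including newline-separated lists of
  trees), Nexus (TREES block with optional TRANSLATE map), PhyloXML,
  NeXML and PhyJSON — all through one generic `read(text, schema)` that
  always returns a list of `Tree` objects.
* **Annotated and extended trees**: BEAST-style `[&key=value,...]` and
  NHX `[&&NHX:key=value:...]` comments land in a per-node annotation
  map; extended-Newick hybrid tags (`#H1`) represent phylogenetic
  networks as multiple node records sharing a hybrid identifier.
  Multifurcations are first-class and never auto-resolved.
* **Scale**: the Newick parser and writer are *iterative* (explicit
  stack, never the call stack), so a tree with 10⁶ tips — or a fully
  pectinate ladder of 10⁵ tips — round-trips without recursion-depth
  failures.
* **Manipulate**: `reroot` (branch-splitting, with a proportion),
  `ladderise`, `get_clade`/`get_subtree`, `get_mrca`, `prune`, `graft`,
  plus node-level `add_child`/`remove_child`, `get_ancestors` and
  pre/post-order traversal.
* **Summarise**: root-to-tip distances and ordinary-least-squares
  root-to-tip regression (molecular-clock rate estimation), tree length,
  Sackin and Colless imbalance indices, the Pybus–Harvey Gamma
  statistic, and the internal/external branch-length (IE) ratio.
* **Simulate**: seeded Yule / caterpillar / balanced tree generation and
  pure-birth ultrametric trees, bit-reproducible across platforms via an
  explicitly specified SplitMix64 RNG.

## The core quantities

For a rooted tree with branch lengths `ℓ(v)` on the edge *into* each
node `v`:

* **IE ratio** = Σ internal `ℓ(v)` / Σ leaf `ℓ(v)` (undefined lengths
  skipped).  An extracted clade keeps its root's incoming branch, which
  counts as internal.
* **Sackin** = Σ over leaves of topological depth; **Colless** =
  Σ over internal nodes of |n(left) − n(right)| (bifurcating trees).
* **Gamma** (Pybus–Harvey): with internode intervals `g_k` (duration
  with `k` lineages) and `T = Σ_j j·g_j`,

  ```
  γ = [ (1/(n−2)) Σ_{i=2}^{n−1} Σ_{j=2}^{i} j·g_j − T/2 ] / ( T·√(1/(12(n−2))) )
  ```

  ≈ 0 under pure birth; requires an ultrametric bifurcating tree.
* **Root-to-tip regression**: OLS of root-to-tip distance on tip time;
  the slope estimates the clock rate.

## Worked example

Annotate each internal node of a four-taxon tree with its clade's IE
ratio, then write the result in the BEAST dialect:

```python
from phylokit import (annotate_ie_ratios, beast_annotation,
                      read_newick, write_newick)

tree = read_newick("((a:2,b:2):1,(c:1,d:1):4);")
annotate_ie_ratios(tree)
print(write_newick(tree, beast_annotation))
```

prints

```
((a:2.0,b:2.0)[&ieRatio="0.25"]:1.0,(c:1.0,d:1.0)[&ieRatio="2.00"]:4.0)[&ieRatio="0.83"];
```

The `{a,b}` cherry has one internal branch (length 1, its own incoming
branch) against external branches 2 + 2, so 1/4 = **0.25**; the `{c,d}`
cherry has 4 against 1 + 1, so **2.00**; the whole tree has 1 + 4
internal against 2 + 2 + 1 + 1 external (the root's length is undefined
and skipped), so 5/6 ≈ **0.83**.

The same tree from the shell:

```
$ echo "((a:2,b:2):1,(c:1,d:1):4);" | phylokit stats
tree    1
treeLength      11.0
sackin  8
colless 0
gamma   NA
ieRatio 0.83
```

`treeLength` is the sum of all defined branch lengths (11); `sackin` is
the sum of the four leaf depths (4 × 2); `colless` 0 because both root
children carry two leaves each; `gamma` is NA because the tree is not
ultrametric.

Rerooting splits a chosen branch (here the branch above node 4, leaf C)
and writes the new root with length 0.0:

```
$ echo "((A:1,B:1):1,C:1);" | phylokit reroot --node-index 4
(C:0.5,(A:1.0,B:1.0):1.5):0.0;
```

Other commands: `convert`, `ladderise`, `extract --mrca a,b`, `prune`,
`rtt --times times.tsv`, `generate`, `bench` (see `phylokit --help`).

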