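# snptree

Infer the hierarchical order of biallelic variants on **non-recombining DNA**
— the human Y chromosome, mitochondrial DNA, haploid pathogen genomes — from
a matrix of ancestral/derived allelic states, even when that matrix is riddled
with missing data.

On DNA that never recombines, variants accumulate along lineages in a strict
hierarchy: each new mutation arises on the background of all earlier ones.
Given individuals typed at a set of polymorphic sites (each call oriented
against an outgroup as ancestral `A` or derived `D`, with `X` for missing),
`snptree` reconstructs that hierarchy as a rooted tree whose branches carry
one or more variants. It is aimed at people who build and maintain
haplogroup-style phylogenies — population, forensic and genetic-genealogy
work — where datasets are stitched together from sources with wildly
different coverage and maximum-likelihood trees become unreliable.

## Method

For every ordered pair of variants *(v₁, v₂)*, restrict v₂'s states to the
individuals in which v₁ is derived. The set of distinct states observed
there confines v₁'s relationship to v₂:

| observed in v₂ | v₁ relative to v₂ is … |
|---|---|
| D | equal, downstream, or upstream |
| D + A | upstream |
| A | parallel or upstream |
| X | parallel, upstream, downstream, or equal |
| D + X | equal, downstream, or upstream |
| A + X | parallel or upstream |
| A + D + X | upstream |

The assessment is repeated with the roles swapped, mirrored
(upstream ↔ downstream) and intersected. A singleton intersection resolves
the pair; an empty intersection is a **contradiction** (recurrent mutation,
backmutation or genotyping error) — the variants causing the most
contradictions are removed one at a time until none remain. The surviving
"v is upstream of w" relations form preliminary branches. Variants whose
order the data cannot resolve are merged into *equal* groups sharing one
branch; variants that could occupy several positions without contradicting
any pairwise relation are removed as *ambiguous* (four pruning scenarios,
iterated to a fixpoint). The groups are then nested into a rooted tree, and
each variant receives a **certainty value**: the fraction of its informative
(upstream/downstream/parallel) pairwise relations consistent with its final
tree position.

Because every pairwise comparison uses whatever cells happen to be typed,
missing data costs resolution but not correctness: relations the method does
assert are supported by observed states, never imputed.

## Worked example

The package ships a 16-variant × 12-individual demonstration matrix:

```
$ python -c "from snptree import demo_matrix; from snptree.matrix_io import write_matrix; write_matrix(demo_matrix(), 'demo.csv')"
$ snptree build demo.csv out/ -contradictory_variants -ambiguous_variants -metadata_individuals
INFO:snptree:input: 16 variants x 12 individuals
INFO:snptree:contradiction pruning removed 1 variant(s)
INFO:snptree:ambiguity pruning removed 4 variant(s); 11 retained in 8 branches (3 at the root)
```

`M16` is a recurrent variant: its pairwise relations are mutually
inconsistent (4 contradictions), so it is removed first. Four more variants
(`M8`, `M13`, `M15`, `M14`) have ambiguous positions and are pruned, each
with its reason in `ambiguous_variants.csv`. The remaining 11 variants form
three main branches, written to `out/tree.csv` as a grid in which the column
of a cell is its depth, equal variants share a cell, and sister clades share
a column:

```
M1, M4	M2, M3
M5	M6, M7
M9	M10	M12
	M11
```

The same topology goes to `out/tree.phyloxml` (clade names like `M1/M4`,
viewable in iTOL), per-variant support to `out/certainty_values.csv` (here
all `1.00`: every informative pairwise relation agrees with the final tree),
and `out/metadata.csv` maps each branch to the individuals carrying its
variants (e.g. `M1, M4 → S1, S2, S3`).

A library call gives the same result in memory:

```python
from snptree import demo_matrix, build_tree
result = build_tree(demo_matrix())
result.removed_contradictory   # ['M16']
result.removed_ambiguous       # ['M8', 'M13', 'M15', 'M14']
len(result.tree.root.children) # 3
```

`snptree simulate` generates matrices from a known random phylogeny with
configurable missingness and planted recurrent mutations, alongside the
ground truth as JSON — the basis of the package's correctness suite.

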