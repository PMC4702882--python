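# ognest

Hierarchically consistent orthologous-group inference from all-vs-all
protein similarity.

## The problem

Orthologs — genes in different species descending from a single gene in
their last common ancestor via speciation — are the workhorse of
comparative genomics: function transfer, phylogenomics and gene-age
estimation all lean on them. Because the "last common ancestor" depends on
which clade you ask about, orthologous groups (OGs) are only meaningful
*per taxonomic level*: two rodent genes may share one mammal-level group
yet belong to two different groups at a narrower level if they duplicated
in between.

`ognest` builds OGs independently at a user-defined set of nested
taxonomic levels from a precomputed all-vs-all matrix of Smith–Waterman
bit-scores, then makes the levels agree with each other. It is aimed at
people who maintain or study orthology resources and want a small,
fully-testable implementation of the graph-based clustering family of
methods, complete with a simulator that knows the true answer.

## What it computes

1. **Per-level clustering** (COG-style). Hits with bit-score ≤ 50 are
   discarded and the rest symmetrized (max of the two directions). Within
   a level, same-species proteins *a, b* are collapsed into an in-paralog
   unit when `s(a,b) ≥ max(bestout(a), bestout(b))`, where `bestout(x)` is
   x's best score to any other species. Units are joined by bidirectional
   best hits (BBH, ties kept); BBH triangles spanning three species are
   merged transitively into OGs; isolated BBH edges survive as two-unit
   groups; curated seed clusters are conserved and extended.
2. **Hierarchical consistency.** Levels are scanned root-ward from the
   leaves. For every child OG divided at the parental level, the species
   overlap of each partition pair is examined largest-to-smallest: no
   shared species ⇒ the parent OGs are merged (the split was an artifact);
   shared species ⇒ a real duplication, and the smaller partition is
   separated into its own OG at the child level and every level below.
   Afterwards every OG nests inside exactly one parent OG.
3. **Pairwise orthology from gene trees.** Internal nodes of a rooted,
   species-tagged gene tree are labeled duplication iff two child subtrees
   share a species (species overlap), else speciation. Cross-species leaf
   pairs with a speciation LCA are orthologs, typed one2one / one2many /
   many2many by counting co-orthologs in the partner species.
4. **Annotation.** Consensus descriptions (most widely shared word n-gram
   among member descriptions), GO/KEGG/SMART/PFAM term frequencies
   relative to annotated members, and root-ward inheritance: unannotated
   groups receive their nearest annotated ancestor's description with an
   explicit `inherited` flag. Viral extras: merging groups that share a
   majority Pfam clan-level domain architecture, and in-silico cleavage of
   polyproteins into their smallest mature chains.
5. **Simulation.** A seeded generator produces an ultrametric species
   tree, nested levels, gene families under per-branch duplication/loss,
   and noisy bit-scores (`S0 − decay·d + N(0, σ)`), together with the true
   per-level OG partition and true event labels — the ground truth every
   other module is tested against.

## Worked example

Simulate a 10-species dataset with known truth, cluster, reconcile, and
derive pairwise orthology:

```sh
ognest simulate --seed 7 --out sim
ognest build     --hits sim/hits.tsv --levels sim/levels.tsv --out run
ognest reconcile --members run/members --levels sim/levels.tsv --out run
ognest orthologs --trees sim/trees --out pairs.tsv
```

`build` logs one line per level:

```
INFO ognest.cli: level Ln3: 4 OGs (0.00s)
INFO ognest.cli: level Ln5: 4 OGs (0.00s)
INFO ognest.cli: level Ln6: 4 OGs (0.00s)
INFO ognest.cli: level Ln9: 3 OGs (0.01s)
```

`Ln9` is the root level (all ten species); it gets exactly one OG per
simulated gene family. The first row of `run/members/Ln9.tsv` —

```
Ln9	0	18	10	s01.f0g1,s01.f0g2,s02.f0g1,...
```

— is an OG with 18 proteins from 10 species: family 0 plus its
within-species duplicates (e.g. `s01.f0g1`/`s01.f0g2`), which the
in-paralog step collapsed into the same group. Narrower levels (`Ln6` =
species s02,s03,s04,s08, etc.) split families where duplications predate
the level's root. `orthologs` prints `224 ortholog pairs written`; the
pair list is typed:

```
family0	s01.f0g1	s02.f0g1	one2one
family0	s01.f0g1	s05.f0g1	one2many
```

`s01.f0g1`–`s05.f0g1` is one-to-many because s01 carries two co-orthologs
of the single s05 gene. The same stages are available from Python
(`ognest.build_ogs`, `ognest.enforce_consistency`,
`GeneTree.pairwise_relations`, ...).

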