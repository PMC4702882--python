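# Methods

This note documents the models, rules and numerical choices behind
`ognest`, and what the simulation-based tests do and do not establish.

## Input model

The pipeline consumes, rather than computes, an all-vs-all protein
similarity matrix: directed hits `(query, subject, bitscore)` with protein
ids of the form `speciesid.proteinid` (species delimited by the first
`.`). Bit-scores are assumed to have been compositionally adjusted
upstream; alignment itself is out of scope. Taxonomic levels are given
explicitly as a table (level id, parent id, species list) and are treated
as authoritative: levels at which orthology is resolved are a curatorial
choice, not something derivable from the data. Validation enforces one
root, acyclic parent links, and every child's species set contained in
its parent's.

## Per-level clustering

**Filter.** Hits with bit-score strictly greater than the threshold
(default 50 bits) are kept. The boundary is deliberately strict and the
threshold configurable; 50 bits is the conventional noise floor for
Smith–Waterman protein comparisons at database scale.

**Symmetrization.** Alignment scores are not exactly symmetric; the
undirected edge takes the maximum of the two directions. Max is monotone
and preserves best-hit relations, which is all the clustering consumes.

**In-paralog units.** Within a level, same-species proteins `a, b` are
linked iff `s(a,b) ≥ max(bestout(a), bestout(b))`, with `bestout(x)` the
best score from `x` to any other species in the level graph (0 if none).
Connected components of linked pairs form the units. This is the standard
"mutually closer to each other than to anything outside the species" rule;
the `≥` (rather than `>`) matters: genes exactly as close to each other as
to the nearest outgroup gene — the signature of a duplication coinciding
with no intervening speciation signal — are collapsed.

**Bidirectional best hits and triangles.** The unit-pair score is the best
member-pair score. `{U, V}` is a BBH iff each is among the other's
best-scoring units in the respective species, *keeping all tied partners*.
Tie-keeping is not an implementation detail: when a duplication postdates
a level's root but predates later speciations, single-copy outgroup genes
are equidistant from both duplicate clades; the tied BBH edges are what
reconnects the two clades into the single group the level's ancestor
implies. BBH triangles spanning three distinct species are merged while
they share an edge; components that end up sharing a unit are merged too,
because groups must partition the level's proteins. BBH edges outside any
triangle still seed groups (their connected components become OGs) so that
two-species levels are not silently empty; units with no surviving edge
remain unclustered and are reported separately rather than emitted as
single-member groups.

**Seeds.** User-supplied curated clusters are conserved: any computed
group intersecting a seed is unioned with every other group that seed
touches and with the seed itself; seed provenance is recorded, and seeds
forced into one group are merged with a warning. Seed members absent from
the level are ignored with a warning.

**Determinism.** Unit ids, merge order and OG ids (base-36 counter over
groups ordered by smallest member id) derive from sorted identifiers;
byte-identical outputs on reruns are asserted in tests.

## Hierarchical consistency

Levels are scanned root-ward from the leaves in a deterministic order
(every level before its parent; ties lexicographic). At each non-root
level, any group whose members fall into two or more parent-level groups
is a split record; its partitions are ordered largest first (ties: more
species first, then the partition containing the lexicographically
smallest member id). Consecutive partition pairs are examined carrying the
survivor forward:

* empty species overlap — the split is treated as a clustering artifact
  and the two *full* parent groups are merged (the alternative, merging
  only the split fragments, would leave the parent level internally
  inconsistent);
* non-empty overlap — the split reflects a real duplication older than
  the child level's root; the smaller partition is removed into its own
  group at the child level and at every deeper level where the two
  partitions still share a group.

The find/resolve cycle iterates to a fixed point per level, and the sweep
over levels repeats until a full pass makes no change; guards abort with a
diagnostic if the number of resolutions at a level exceeds the number of
clustered proteins. Merging at the parental level propagates further
root-ward when the scan reaches that level, not recursively. After
enforcement the nesting invariant — every group wholly inside one parent
group, members unclustered at the parent excepted — is asserted
unconditionally; gene-fusion proteins, which legitimately straddle groups,
are not modeled. Proteins are never dropped, only regrouped, and
enforcement is idempotent (tested).

## Gene-tree orthology

Gene trees are consumed as rooted Newick with species-tagged leaves
(trees are built upstream; trifurcating roots are rejected unless
explicitly forced). Each internal node is labeled **duplication** iff at
least two of its child subtrees share a species, else **speciation**;
multifurcations are treated as simultaneous splits. The rule is exact on
true histories without gene loss; with losses it can mislabel (a
duplication whose one copy lost all overlapping species looks like a
speciation) — this error is measured on simulations, not assumed away.

Leaf pairs are classified by their LCA: same species → in-paralogs;
different species with speciation LCA → orthologs; different species with
duplication LCA → out-paralogs (reported separately, excluded from the
ortholog list). Ortholog pairs are typed by co-ortholog counts: with
`n_a` = number of a's orthologs in b's species and vice versa, the pair is
one2one (both 1), one2many (exactly one is 1), else many2many.

## Annotation

**Consensus description.** Member descriptions are lowercased, tokenized,
stripped of punctuation, and filtered against a stop-list ("protein",
"putative", "hypothetical", "uncharacterized", "predicted", "conserved",
plus function words), pure numbers and accession-like tokens. The summary
is the word n-gram over the filtered token sequences that occurs in the
most descriptions (then longest in words, then in characters, then
lexicographically first); n-grams present in fewer than two descriptions
never qualify, so nothing shared yields an empty summary. A single
annotated member is returned verbatim. The procedure is deterministic and
idempotent.

**Profiles.** Term frequencies (GO, KEGG, SMART, PFAM namespaces) are
counted per group relative to the members carrying at least one term in
that namespace — not the full membership — so sparsely annotated groups
remain comparable. Frequencies times the annotated-member count are
integers by construction.

**Inheritance.** On a consistent hierarchy, a group with an empty
description inherits description and COG category letters from its nearest
annotated ancestor group (found by member containment), processed
root-first so chains of unannotated ancestors resolve in one pass. Every
transfer is flagged `inherited` in all outputs so applications can exclude
them. COG category letters are bookkept and propagated but never
predicted: training a functional classifier is out of scope.

**Viral steps.** Groups whose strict majority (>50 % of members with a
non-empty architecture) share an identical ordered Pfam clan-id sequence
are merged; order sensitivity is a deliberate choice since domain order is
part of the architecture. Polyproteins are cleaved at 1-based inclusive
chain coordinates; a chain strictly containing another is discarded so
only smallest mature units remain, and identical extracted sequences are
deduplicated.

## Simulator

The generator exists to give every other module a ground truth.

* **Species tree:** uniformly random sequential joins; the k-th join is
  one time unit older than the previous, so the tree is ultrametric with
  all extant species at the same depth and every internal node at a
  distinct integer depth. Ultrametricity is the realistic choice (extant
  species are contemporaneous) and is what makes similarity scores
  clock-like; without it, path-length distance and divergence time
  disagree and no score-based method can recover the true groups even
  noise-free.
* **Levels:** the root plus a random sample of internal nodes; species
  sets are subtree leaves, so nesting holds by construction.
* **Families:** one ancestral gene at the root; along each branch a
  lineage is lost with probability 1−e^(−μ) then, if surviving,
  duplicated with probability 1−e^(−λ) (at most one event of each kind
  per lineage per branch — adequate for the small per-branch rates used).
  Duplications are placed 0.25 time units above the receiving node so
  duplication depths never coincide with speciation depths and no
  spurious score ties arise. Lost lineages are pruned, unary nodes
  suppressed. The true per-level partition groups extant genes by their
  ancestral copy at the level's root node and is nested across levels by
  construction.
* **Scores:** `bitscore = S0 − decay·d(a,b) + N(0, σ)`, floored at 0,
  both directions with independent noise. This emulates the *rank
  geometry* of bit-scores, not sequence evolution: no rate heterogeneity,
  no compositional effects, no horizontal transfer. Defaults: 10 species,
  4 levels, λ = 0.1 and μ = 0.05 per branch, S0 = 500 bits, decay = 10
  bits per time unit, σ = 5 bits, 3 families per dataset — a regime where
  within-family scores stay far above the 50-bit floor and noise is large
  enough to provoke genuine cross-level disagreements for the consistency
  pass to repair.

Consequently, passing tests show the algorithms are correct relative to
their own model of the data (clock-like scores, tree-like evolution).
They do not certify performance on real proteomes, where rate variation,
domain shuffling, fusions and annotation errors violate that model; the
OG quality achievable there is an empirical question outside this
package's scope.

## Evaluation conventions

Partition recovery is scored by pair precision/recall/F over co-membership
pairs (ortholog-pair lists are compared as pair sets directly). An empty
prediction has precision 1.0 by convention (nothing asserted), an empty
truth recall 1.0. Robustness of tree-derived orthology is probed by
nearest-neighbour interchanges applied to 10 % of eligible internal edges
followed by species-overlap relabeling.

## Known limitations

* The "split again on reciprocal best hits between separate lineages"
  refinement sometimes described for graph clustering is not implemented
  as a distinct pass; all cross-level corrections happen in the
  consistency stage.
* Chains of non-triangle BBH edges collapse into a single group rather
  than a sequence of two-unit groups; with tie-keeping this is the only
  assignment that keeps groups disjoint without an arbitrary edge order.
* Gene fusions are not exempted from the nesting invariant.
* Unclustered singletons are reported separately, not emitted as
  single-member groups.
* The simulator does not model horizontal transfer, rate heterogeneity or
  sequence content; score noise is i.i.d. Gaussian.
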