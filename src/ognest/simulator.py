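"""Gene-family simulation with known duplication/loss history.

To test clustering, reconciliation and tree analysis without a proteome
corpus, this module simulates: (i) a random rooted species tree whose
internal nodes supply nested taxonomic levels; (ii) gene families evolving
along that tree under a per-branch birth–death process (each lineage is
lost with probability 1−e^(−μ) and duplicates with probability 1−e^(−λ)
per branch); (iii) all-vs-all similarity bit-scores that decay linearly
with gene-tree distance plus Gaussian noise. The true orthologous-group
partition at each level is recorded during simulation: extant genes are
grouped by the ancestral gene copy present at the level's root node, which
makes the ground truth hierarchically nested by construction.

Scores are a rank-structure emulation, not a sequence-evolution model:
the clustering consumes only bit-scores, so reproducing their geometry
(closer relatives score higher) is what matters for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .og_builder import OGSet
from .simgraph import Hit, species_of
from .taxonomy import LevelHierarchy, TaxLevel
from .tree_orthology import GeneTree, parse_gene_tree


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    n_species: int = 10
    n_levels: int = 4
    dup_rate: float = 0.1      # λ: expected duplications per branch
    loss_rate: float = 0.05    # μ: expected losses per branch
    score_base: float = 500.0  # S0: bits at zero divergence
    decay: float = 10.0        # bits lost per unit tree distance
    noise_sd: float = 5.0      # Gaussian score noise, bits
    n_families: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_levels < 1:
            raise ValueError("need at least 1 level")
        if min(self.dup_rate, self.loss_rate, self.noise_sd) < 0:
            raise ValueError("rates must be non-negative")


# ---------------------------------------------------------------------------
# species tree


class SpNode:
    """Species-tree node.

    depth is the time distance from the root; the tree is ultrametric
    (all leaves share the same depth), as extant species are
    contemporaneous — this is what makes similarity scores clock-like.
    """

    __slots__ = ("id", "children", "depth")

    def __init__(self, id: str, children: list["SpNode"] | None = None,
                 depth: float = 0.0):
        self.id = id
        self.children = children or []
        self.depth = depth

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_ids(self) -> list[str]:
        if self.is_leaf:
            return [self.id]
        return [x for c in self.children for x in c.leaf_ids()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class SpeciesTree:
    root: SpNode
    #: level id → species-tree node rooting that level
    level_nodes: dict[str, SpNode] = field(default_factory=dict)


def simulate_taxonomy(cfg: SimConfig) -> tuple[LevelHierarchy, SpeciesTree]:
    """Random rooted species tree plus a nested level hierarchy.

    The topology is built by uniformly random sequential joins (a
    coalescent-style shape); the k-th join happens one time unit before
    the (k−1)-th, giving an ultrametric tree with all leaves at depth
    n_species − 1 and every internal node at a distinct integer depth.
    ``n_levels`` internal nodes are designated as taxonomic levels (the
    root always among them); each level's species set is its subtree's
    leaves, so the subset invariant holds by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_species))
    nodes: list[SpNode] = [
        SpNode(f"s{i + 1:0{width}d}") for i in range(cfg.n_species)
    ]
    height = {n.id: 0 for n in nodes}  # time before present
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        counter += 1
        joined = SpNode(f"n{counter}", [nodes[i], nodes[j]])
        height[joined.id] = counter
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(joined)
    root = nodes[0]

    total = height[root.id]
    for node in root.walk():
        node.depth = float(total - height[node.id])

    internal = [n for n in root.walk() if not n.is_leaf]
    if cfg.n_levels > len(internal):
        raise ValueError(
            f"n_levels={cfg.n_levels} exceeds internal node count {len(internal)}"
        )
    others = [n for n in internal if n is not root]
    picked_idx = rng.choice(len(others), size=cfg.n_levels - 1, replace=False) \
        if cfg.n_levels > 1 else []
    chosen = {root.id: root}
    for k in sorted(int(i) for i in picked_idx):
        chosen[others[k].id] = others[k]

    # parent of each level = nearest chosen ancestor
    levels: list[TaxLevel] = []
    level_nodes: dict[str, SpNode] = {}

    def assign(node: SpNode, nearest: str | None) -> None:
        if node.id in chosen:
            lid = f"L{node.id}"
            levels.append(
                TaxLevel(id=lid, parent=f"L{nearest}" if nearest else None,
                         species=set(node.leaf_ids()))
            )
            level_nodes[lid] = node
            nearest = node.id
        for c in node.children:
            assign(c, nearest)

    assign(root, None)
    return LevelHierarchy(levels), SpeciesTree(root=root, level_nodes=level_nodes)


# ---------------------------------------------------------------------------
# gene-family birth–death simulation


class _GNode:
    __slots__ = ("event", "children", "name", "depth")

    def __init__(self, event=None, children=None, name=None, depth=0.0):
        self.event = event          # "speciation" | "duplication" | None (leaf)
        self.children = children or []
        self.name = name            # leaf gene name
        self.depth = depth

    def leaves(self) -> list["_GNode"]:
        if not self.children:
            return [self]
        return [x for c in self.children for x in c.leaves()]


class ExtinctFamilyError(RuntimeError):
    pass


@dataclass
class TrueFamily:
    """One simulated gene family with its complete true history."""

    gene_tree: GeneTree                     # true speciation/duplication labels
    extant: list[str]                       # gene names, "species.gene"
    #: level id → ground-truth OG partition (list of frozen member sets)
    groups_per_level: dict[str, list[frozenset[str]]]
    #: gene-tree distance between every extant pair
    distances: dict[frozenset[str], float]
    #: cross-species pairs whose true LCA is a speciation event
    true_ortholog_pairs: set[frozenset[str]]


def simulate_family(
    species_tree: SpeciesTree,
    cfg: SimConfig,
    family_index: int = 0,
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
    force_root_duplication: bool = False,
) -> TrueFamily:
    """Evolve one gene family along the species tree.

    A single ancestral gene sits at the root. Along each branch every gene
    lineage is first lost with probability 1−e^(−μ), then (if surviving)
    duplicated with probability 1−e^(−λ); a duplication is placed just
    above the branch's end node (0.25 time units, so duplication depths
    never coincide with speciation depths) and both copies continue
    independently. Lost lineages are pruned and unary nodes suppressed, so
    the returned tree contains only observable events. Families going
    extinct (fewer than 2 extant genes) are resampled up to
    ``max_retries`` times.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 7919 * (family_index + 1))
    p_loss = 1.0 - math.exp(-cfg.loss_rate)
    p_dup = 1.0 - math.exp(-cfg.dup_rate)

    group_sink: dict[str, list[list[_GNode]]] = {}
    node_of_level = species_tree.level_nodes

    def continue_at(sp: SpNode) -> _GNode | None:
        # one ancestral gene copy present exactly at species-tree node sp
        if sp.is_leaf:
            sub: _GNode | None = _GNode(name=sp.id, depth=float(sp.depth))
        else:
            kids = [branch(c) for c in sp.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                sub = None
            elif len(kids) == 1:
                sub = kids[0]
            else:
                sub = _GNode(event="speciation", children=kids,
                             depth=float(sp.depth))
        if sub is not None:
            for lid, node in node_of_level.items():
                if node is sp:
                    group_sink.setdefault(lid, []).append(sub.leaves())
        return sub

    def branch(sp_child: SpNode) -> _GNode | None:
        if rng.random() < p_loss:
            return None
        if rng.random() < p_dup:
            a = continue_at(sp_child)
            b = continue_at(sp_child)
            if a is not None and b is not None:
                return _GNode(event="duplication", children=[a, b],
                              depth=sp_child.depth - 0.25)
            return a if a is not None else b
        return continue_at(sp_child)

    def sample_root() -> _GNode | None:
        if not force_root_duplication:
            return continue_at(species_tree.root)
        # two ancestral copies, duplicated just above the species root
        a = continue_at(species_tree.root)
        b = continue_at(species_tree.root)
        if a is not None and b is not None:
            return _GNode(event="duplication", children=[a, b],
                          depth=species_tree.root.depth - 0.25)
        return a if a is not None else b

    for _ in range(max_retries):
        group_sink.clear()
        root = sample_root()
        if root is not None and len(root.leaves()) >= 2:
            break
    else:
        raise ExtinctFamilyError(
            f"family went extinct in {max_retries} consecutive attempts"
        )

    # name extant genes deterministically: per-species counters, left-to-right
    counters: dict[str, int] = {}
    for leaf in root.leaves():
        sp = leaf.name
        counters[sp] = counters.get(sp, 0) + 1
        leaf.name = f"{sp}.f{family_index}g{counters[sp]}"

    # pairwise gene-tree distances and true-orthology from the raw structure
    distances: dict[frozenset[str], float] = {}
    true_orth: set[frozenset[str]] = set()

    def collect(node: _GNode) -> list[_GNode]:
        if not node.children:
            return [node]
        per_child = [collect(c) for c in node.children]
        for i in range(len(per_child)):
            for j in range(i + 1, len(per_child)):
                for a in per_child[i]:
                    for b in per_child[j]:
                        key = frozenset((a.name, b.name))
                        distances[key] = (
                            (a.depth - node.depth) + (b.depth - node.depth)
                        )
                        if (
                            node.event == "speciation"
                            and species_of(a.name) != species_of(b.name)
                        ):
                            true_orth.add(key)
        return [x for sub in per_child for x in sub]

    collect(root)

    def newick(node: _GNode) -> str:
        if not node.children:
            return node.name
        label = "S" if node.event == "speciation" else "D"
        return "(" + ",".join(newick(c) for c in node.children) + ")" + label

    gene_tree = parse_gene_tree(newick(root) + ";", force_root=True,
                                read_labels=True)

    groups = {
        lid: [
            frozenset(leaf.name for leaf in grp)
            for grp in grps
            if grp
        ]
        for lid, grps in group_sink.items()
    }
    # levels whose root node the family never reached (it must: root is a
    # level and the family survived) still need an entry
    for lid in node_of_level:
        groups.setdefault(lid, [])

    return TrueFamily(
        gene_tree=gene_tree,
        extant=sorted(leaf.name for leaf in root.leaves()),
        groups_per_level=groups,
        distances=distances,
        true_ortholog_pairs=true_orth,
    )


# ---------------------------------------------------------------------------
# similarity scores


def scores_from_family(
    fam: TrueFamily,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[Hit]:
    """Noisy all-vs-all bit-scores for one family.

    Both directions of every extant pair are emitted with independent
    Gaussian noise: ``bitscore = S0 − decay·d(a,b) + N(0, noise_sd)``,
    floored at 0.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    hits: list[Hit] = []
    genes = fam.extant
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            d = fam.distances[frozenset((a, b))]
            base = cfg.score_base - cfg.decay * d
            for q, s in ((a, b), (b, a)):
                noise = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
                hits.append(Hit(q, s, max(0.0, base + noise)))
    return hits


# ---------------------------------------------------------------------------
# whole datasets


@dataclass
class Dataset:
    cfg: SimConfig
    hierarchy: LevelHierarchy
    species_tree: SpeciesTree
    families: list[TrueFamily]
    hits: list[Hit]

    def truth_partition(self, level_id: str) -> list[frozenset[str]]:
        """Ground-truth OG partition at a level, pooled over families."""
        out: list[frozenset[str]] = []
        for fam in self.families:
            out.extend(fam.groups_per_level.get(level_id, []))
        return out


def simulate_dataset(cfg: SimConfig) -> Dataset:
    """Taxonomy + ``cfg.n_families`` families + pooled noisy hits.

    Families are unrelated, so no between-family hits are emitted (their
    similarity would fall below any sensible threshold).
    """
    hierarchy, sptree = simulate_taxonomy(cfg)
    score_rng = np.random.default_rng(cfg.seed + 104729)
    families = []
    hits: list[Hit] = []
    for k in range(cfg.n_families):
        fam = simulate_family(sptree, cfg, family_index=k)
        families.append(fam)
        hits.extend(scores_from_family(fam, cfg, rng=score_rng))
    return Dataset(cfg=cfg, hierarchy=hierarchy, species_tree=sptree,
                   families=families, hits=hits)


# ---------------------------------------------------------------------------
# topology perturbation (for robustness experiments)


def perturb_nni(
    tree: GeneTree,
    fraction: float = 0.1,
    rng: np.random.Generator | None = None,
) -> GeneTree:
    """Random nearest-neighbour interchanges on a fraction of internal edges.

    Returns a new, unlabeled tree; event labels must be recomputed. Trees
    too small to have an eligible internal edge are returned unchanged
    (as a copy).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    out = parse_gene_tree(tree.to_newick(labels=False), force_root=True,
                          read_labels=False)
    t = out.tree
    eligible = [
        n for n in t.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None
        and len(n.child_nodes()) >= 2 and len(n.parent_node.child_nodes()) >= 2
    ]
    if not eligible:
        return out
    k = int(round(fraction * len(eligible)))
    if k == 0:
        return out
    idx = rng.choice(len(eligible), size=min(k, len(eligible)), replace=False)
    for i in sorted(int(x) for x in idx):
        v = eligible[i]
        u = v.parent_node
        siblings = [c for c in u.child_nodes() if c is not v]
        w = siblings[int(rng.integers(len(siblings)))]
        kids = v.child_nodes()
        x = kids[int(rng.integers(len(kids)))]
        u.remove_child(w)
        v.remove_child(x)
        u.add_child(x)
        v.add_child(w)
    return parse_gene_tree(out.to_newick(labels=False), force_root=True,
                           read_labels=False)


# ---------------------------------------------------------------------------
# recovery metrics


def _comembership_pairs(groups: Iterable[Iterable[str]]) -> set[frozenset[str]]:
    pairs: set[frozenset[str]] = set()
    for grp in groups:
        members = sorted(grp)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pairs.add(frozenset((a, b)))
    return pairs


def pair_prf(
    predicted: set[frozenset[str]], truth: set[frozenset[str]]
) -> tuple[float, float, float]:
    """Pair-level precision, recall, F-measure.

    Convention: an empty prediction has precision 1.0 (nothing asserted,
    nothing wrong); an empty truth has recall 1.0.
    """
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f


def evaluate_recovery(
    predicted: OGSet | Iterable[Iterable[str]] | set[frozenset[str]],
    truth: Sequence[Iterable[str]] | set[frozenset[str]],
) -> tuple[float, float, float]:
    """Precision/recall/F of predicted vs true groupings or pair sets.

    OGSets and group lists are compared by co-membership pairs; sets of
    frozenset pairs are compared directly. Raises if the gene universes
    are disjoint (a sign of mismatched inputs).
    """
    def to_pairs(x) -> tuple[set[frozenset[str]], set[str]]:
        if isinstance(x, OGSet):
            groups = [og.members for og in x.groups]
            return _comembership_pairs(groups), {m for g in groups for m in g}
        x = list(x)
        if x and isinstance(next(iter(x)), frozenset) and all(
            len(e) == 2 for e in x
        ):
            return set(x), {m for e in x for m in e}
        return _comembership_pairs(x), {m for g in x for m in g}

    pred_pairs, pred_universe = to_pairs(predicted)
    true_pairs, true_universe = to_pairs(truth)
    if pred_universe and true_universe and not (pred_universe & true_universe):
        raise ValueError("predicted and true gene universes are disjoint")
    return pair_prf(pred_pairs, true_pairs)


# ---------------------------------------------------------------------------
# fixture bundle export


def write_fixture_bundle(dataset: Dataset, outdir: str | Path) -> None:
    """Write a dataset in the exact input formats of the other modules.

    Produces ``levels.tsv``, ``hits.tsv``, ``truth_members.tsv`` and one
    labeled Newick per family under ``trees/``.
    """
    from . import og_builder, simgraph, taxonomy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "levels.tsv", "w", encoding="utf-8") as fh:
        taxonomy.write_hierarchy(dataset.hierarchy, fh)
    with open(outdir / "hits.tsv", "w", encoding="utf-8") as fh:
        simgraph.write_hits(dataset.hits, fh)
    with open(outdir / "truth_members.tsv", "w", encoding="utf-8") as fh:
        for lid in sorted(dataset.hierarchy.levels):
            ogset = OGSet(level=lid)
            for i, members in enumerate(
                sorted(dataset.truth_partition(lid), key=lambda g: min(g))
            ):
                ogset.groups.append(
                    og_builder.OG(id=og_builder._base36(i), level=lid,
                                  members=set(members))
                )
            og_builder.write_members([ogset], fh)
    treedir = outdir / "trees"
    treedir.mkdir(exist_ok=True)
    for k, fam in enumerate(dataset.families):
        with open(treedir / f"family{k}.nwk", "w", encoding="utf-8") as fh:
            fh.write(fam.gene_tree.to_newick(labels=True))
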