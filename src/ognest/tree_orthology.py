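"""Gene-tree event labeling and fine-grained pairwise orthology.

Within an orthologous group, relationships at the resolution of individual
gene pairs are derived from a rooted gene tree. Internal nodes are labeled
speciation or duplication by the species-overlap rule: a node is a
duplication iff at least two of its child subtrees share a species —
a gene family can only contain the same species on both sides of a split
if the split was a duplication. Leaf pairs whose last common ancestor is a
speciation are orthologs and are typed one-to-one / one-to-many /
many-to-many by counting each gene's co-orthologs in the partner species;
pairs joined by a duplication are (in-)paralogs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import IO, Iterable, Literal

import dendropy

from .simgraph import species_of

SPECIATION = "speciation"
DUPLICATION = "duplication"

Relation = Literal["one2one", "one2many", "many2many"]


class GeneTreeError(ValueError):
    pass


@dataclass(frozen=True)
class OrthologPair:
    a: str
    b: str
    relation: Relation


@dataclass(frozen=True)
class InparalogPair:
    a: str
    b: str


@dataclass(frozen=True)
class ParalogPair:
    """Cross-species pair whose LCA is a duplication (out-paralogs)."""

    a: str
    b: str


class GeneTree:
    """A rooted gene tree with species-tagged leaves and event labels.

    Leaves are named ``speciesid.proteinid``; internal nodes carry an
    ``event`` attribute (speciation / duplication / None). Backed by a
    dendropy Tree.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        leaves = self.leaf_names()
        if len(leaves) < 2:
            raise GeneTreeError("gene tree needs at least 2 leaves")
        if len(set(leaves)) != len(leaves):
            raise GeneTreeError("duplicate leaf names")
        for name in leaves:
            species_of(name)  # raises if no species prefix
        for node in self.tree:
            if not hasattr(node, "event"):
                node.event = None

    # -- basics ---------------------------------------------------------

    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def species(self) -> set[str]:
        return {species_of(n) for n in self.leaf_names()}

    def internal_nodes(self):
        return [n for n in self.tree.preorder_node_iter() if not n.is_leaf()]

    # -- event labeling ---------------------------------------------------

    def label_events(self) -> "GeneTree":
        """Label every internal node by species overlap (in place).

        Multifurcations are treated as simultaneous: the node is a
        duplication iff any two of its child subtrees share a species.
        """
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node._sp = {species_of(node.taxon.label)}
                continue
            child_sets = [c._sp for c in node.child_nodes()]
            seen: set[str] = set()
            dup = False
            for cs in child_sets:
                if seen & cs:
                    dup = True
                seen |= cs
            node.event = DUPLICATION if dup else SPECIATION
            node._sp = seen
        return self

    # -- pairwise relations ----------------------------------------------

    def pairwise_relations(
        self,
    ) -> tuple[list[OrthologPair], list[InparalogPair], list[ParalogPair]]:
        """Classify every leaf pair from the labeled tree.

        Cross-species pairs with a speciation LCA are orthologs; pairs of
        the same species are in-paralogs; cross-species pairs with a
        duplication LCA are out-paralogs (excluded from ortholog output).
        Requires all internal nodes labeled (run :meth:`label_events` or
        use true simulation labels).
        """
        for node in self.internal_nodes():
            if node.event not in (SPECIATION, DUPLICATION):
                raise GeneTreeError("tree has unlabeled internal nodes")

        orth_partners: dict[str, set[str]] = {n: set() for n in self.leaf_names()}
        inpara: list[InparalogPair] = []
        outpara: list[ParalogPair] = []

        # every leaf pair's LCA is the internal node whose distinct child
        # subtrees contain the two leaves
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node._leaves = [node.taxon.label]
                continue
            kids = [c._leaves for c in node.child_nodes()]
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    for a, b in product(kids[i], kids[j]):
                        a2, b2 = sorted((a, b))
                        same_sp = species_of(a2) == species_of(b2)
                        if same_sp:
                            inpara.append(InparalogPair(a2, b2))
                        elif node.event == SPECIATION:
                            orth_partners[a2].add(b2)
                            orth_partners[b2].add(a2)
                        else:
                            outpara.append(ParalogPair(a2, b2))
            node._leaves = [x for k in kids for x in k]

        orthologs: list[OrthologPair] = []
        for a in sorted(orth_partners):
            for b in sorted(orth_partners[a]):
                if a >= b:
                    continue
                n_a = sum(
                    1 for x in orth_partners[a] if species_of(x) == species_of(b)
                )
                n_b = sum(
                    1 for x in orth_partners[b] if species_of(x) == species_of(a)
                )
                if n_a == 1 and n_b == 1:
                    rel: Relation = "one2one"
                elif n_a == 1 or n_b == 1:
                    rel = "one2many"
                else:
                    rel = "many2many"
                orthologs.append(OrthologPair(a, b, rel))
        return orthologs, sorted(inpara, key=lambda p: (p.a, p.b)), sorted(
            outpara, key=lambda p: (p.a, p.b)
        )

    # -- serialization ----------------------------------------------------

    def to_newick(self, labels: bool = True) -> str:
        """Newick string; internal node labels S/D encode event labels."""
        if labels:
            for node in self.internal_nodes():
                if node.event == SPECIATION:
                    node.label = "S"
                elif node.event == DUPLICATION:
                    node.label = "D"
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
            + "\n"
        ).replace("'", "")


_EVENT_CODES = {"S": SPECIATION, "D": DUPLICATION,
                SPECIATION: SPECIATION, DUPLICATION: DUPLICATION}


def parse_gene_tree(
    newick: str | IO[str],
    force_root: bool = False,
    read_labels: bool = True,
) -> GeneTree:
    """Parse a rooted Newick gene tree.

    A trifurcating root is taken as unrooted and rejected unless
    ``force_root`` is set (the multifurcation is then treated as a real
    polytomy). Internal node labels ``S``/``D`` are read back as event
    labels when ``read_labels`` is true.
    """
    text = newick.read() if hasattr(newick, "read") else newick
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise GeneTreeError(f"malformed Newick: {exc}") from exc
    n_root_children = len(tree.seed_node.child_nodes())
    if n_root_children > 2 and not force_root:
        raise GeneTreeError(
            f"unrooted input: root has {n_root_children} children "
            "(pass force_root to accept)"
        )
    for node in tree:
        node.event = None
        if read_labels and not node.is_leaf() and node.label in _EVENT_CODES:
            node.event = _EVENT_CODES[node.label]
    return GeneTree(tree)


def label_events(t: GeneTree) -> GeneTree:
    """Module-level convenience wrapper for :meth:`GeneTree.label_events`."""
    return t.label_events()


def pairwise_relations(t: GeneTree):
    """Module-level convenience wrapper for :meth:`GeneTree.pairwise_relations`."""
    return t.pairwise_relations()


def write_pairs(
    rows: Iterable[tuple[str, OrthologPair]], stream: IO[str]
) -> None:
    """Pairwise TSV: og_id, protein_a, protein_b, relation."""
    for og_id, pair in rows:
        stream.write(f"{og_id}\t{pair.a}\t{pair.b}\t{pair.relation}\n")


def read_pairs(stream: IO[str] | Iterable[str]) -> list[tuple[str, OrthologPair]]:
    out = []
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        og_id, a, b, rel = line.split("\t")
        out.append((og_id, OrthologPair(a, b, rel)))  # type: ignore[arg-type]
    return out
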