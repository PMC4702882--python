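"""Build orthologous groups at one taxonomic level.

The clustering follows the COG-style graph heuristic: proteins of the same
species that are mutually closer to each other than to anything outside
their species are collapsed into in-paralog units; units are connected by
bidirectional best hits (BBH) across species; triangles of BBH edges
spanning three species are merged into clusters; user-supplied seed
clusters (curated groups at their native level) are conserved and extended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import networkx as nx

from .simgraph import HitGraph, species_of
from .taxonomy import TaxLevel

log = logging.getLogger(__name__)


def _base36(n: int) -> str:
    digits = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if n == 0:
        return "0"
    out = []
    while n:
        n, r = divmod(n, 36)
        out.append(digits[r])
    return "".join(reversed(out))


@dataclass(frozen=True)
class InparalogGroup:
    """Same-species proteins that duplicated after the level's last speciation.

    Members are linked when their within-species score is at least as high
    as either member's best score to any other species. Singletons allowed.
    """

    id: str
    species: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        assert self.members, "in-paralog group must be non-empty"
        assert all(species_of(m) == self.species for m in self.members)


@dataclass
class OG:
    """One orthologous group at a taxonomic level."""

    id: str
    level: str
    members: set[str]
    seed_origin: tuple[str, ...] = ()

    @property
    def species(self) -> set[str]:
        return {species_of(m) for m in self.members}


@dataclass
class OGSet:
    """The orthologous groups of one level (a partial partition).

    Groups are pairwise disjoint; proteins that did not cluster remain
    outside and are listed in ``unclustered``.
    """

    level: str
    groups: list[OG] = field(default_factory=list)
    unclustered: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def membership(self) -> dict[str, str]:
        """protein id → OG id for all clustered proteins."""
        out: dict[str, str] = {}
        for og in self.groups:
            for m in og.members:
                assert m not in out, f"protein {m} in two OGs at level {self.level}"
                out[m] = og.id
        return out

    def assert_disjoint(self) -> None:
        self.membership()


# ---------------------------------------------------------------------------
# in-paralog detection


def detect_inparalogs(g: HitGraph, level: TaxLevel) -> list[InparalogGroup]:
    """Collapse same-species proteins into in-paralog units.

    Two proteins a, b of the same species are linked iff
    ``score(a,b) >= max(bestout(a), bestout(b))`` where ``bestout(x)`` is
    x's highest score to any protein of another species in the level graph
    (0 if none). Units are the connected components of the linked pairs;
    every protein of the level appears in exactly one unit (possibly a
    singleton).
    """
    g = g.restrict_to_level(level)
    bestout: dict[str, float] = {}
    for p in g.proteins:
        sp = g.species(p)
        bestout[p] = max(
            (w for _, nbr, w in g.graph.edges(p, data="weight")
             if g.species(nbr) != sp),
            default=0.0,
        )

    linked = nx.Graph()
    linked.add_nodes_from(g.proteins)
    for a, b, w in g.edges():
        if g.species(a) == g.species(b) and w >= max(bestout[a], bestout[b]):
            linked.add_edge(a, b)

    units: list[InparalogGroup] = []
    comps = sorted(nx.connected_components(linked), key=min)
    for i, comp in enumerate(comps):
        members = frozenset(comp)
        units.append(
            InparalogGroup(
                id=f"u{_base36(i)}",
                species=g.species(min(comp)),
                members=members,
            )
        )
    return units


# ---------------------------------------------------------------------------
# bidirectional best hits between units


def unit_score(u: InparalogGroup, v: InparalogGroup, g: HitGraph) -> float:
    """Score between two units: best member-pair score (0 if none)."""
    return max((g.score(a, b) for a in u.members for b in v.members), default=0.0)


def unit_best_hits(
    units: Sequence[InparalogGroup], g: HitGraph
) -> set[frozenset[str]]:
    """Bidirectional best hits between in-paralog units of different species.

    {U, V} is emitted iff V is among U's best-scoring units in V's species
    and U is among V's best-scoring units in U's species (ties keep all
    tied best partners). Returns unordered pairs of unit ids.
    """
    by_id = {u.id: u for u in units}
    # best partners of each unit per foreign species
    best: dict[tuple[str, str], set[str]] = {}
    scores: dict[frozenset[str], float] = {}
    for i, u in enumerate(units):
        for v in units[i + 1:]:
            if u.species == v.species:
                continue
            s = unit_score(u, v, g)
            if s > 0:
                scores[frozenset((u.id, v.id))] = s

    best_score: dict[tuple[str, str], float] = {}
    for pair, s in scores.items():
        a, b = sorted(pair)
        for u_id, v_id in ((a, b), (b, a)):
            key = (u_id, by_id[v_id].species)
            if s > best_score.get(key, 0.0):
                best_score[key] = s
                best[key] = {v_id}
            elif s == best_score.get(key):
                best[key].add(v_id)

    out: set[frozenset[str]] = set()
    for pair in scores:
        u_id, v_id = sorted(pair)
        if (
            v_id in best.get((u_id, by_id[v_id].species), ())
            and u_id in best.get((v_id, by_id[u_id].species), ())
        ):
            out.add(pair)
    return out


# ---------------------------------------------------------------------------
# triangle merging


def triangle_merge(
    bbh: set[frozenset[str]],
    units: Sequence[InparalogGroup],
    level: TaxLevel,
) -> OGSet:
    """Merge BBH triangles spanning three species into orthologous groups.

    Triangles of BBH edges over three distinct species are detected and
    iteratively merged while they share an edge (transitively, components
    sharing a unit are merged too, so groups stay disjoint). BBH edges
    between different species that take part in no triangle still seed
    groups: their connected components (outside any triangle cluster)
    become OGs, so a level with only two species still yields groups.
    Units left isolated remain unclustered.
    """
    by_id = {u.id: u for u in units}
    ug = nx.Graph()
    ug.add_nodes_from(by_id)
    for pair in bbh:
        a, b = sorted(pair)
        ug.add_edge(a, b)

    merged = nx.utils.UnionFind(by_id.keys())
    in_triangle: set[str] = set()
    for a, b in ug.edges():
        for c in sorted(nx.common_neighbors(ug, a, b)):
            species = {by_id[a].species, by_id[b].species, by_id[c].species}
            if len(species) == 3:
                merged.union(a, b)
                merged.union(b, c)
                in_triangle.update((a, b, c))

    # fallback: non-triangle inter-species BBH edges between unclustered units
    for a, b in sorted(tuple(sorted(p)) for p in bbh):
        if a not in in_triangle and b not in in_triangle:
            merged.union(a, b)

    clusters: dict[str, set[str]] = {}
    for uid in by_id:
        root = merged[uid]
        clusters.setdefault(root, set()).add(uid)

    ogset = OGSet(level=level.id)
    groups: list[set[str]] = []
    singles: list[str] = []
    for cluster in clusters.values():
        if len(cluster) < 2:
            (uid,) = cluster
            singles.extend(by_id[uid].members)
            continue
        groups.append({m for uid in cluster for m in by_id[uid].members})
    ogset.unclustered = sorted(singles)
    for i, members in enumerate(sorted(groups, key=min)):
        ogset.groups.append(OG(id=_base36(i), level=level.id, members=members))
    ogset.assert_disjoint()
    return ogset


# ---------------------------------------------------------------------------
# seed conservation


def extend_seeds(
    ogset: OGSet,
    seeds: Iterable[OG],
    universe: set[str] | None = None,
) -> OGSet:
    """Conserve seed clusters: never break a seed's co-membership.

    Every computed OG intersecting a seed is unioned with all other OGs
    intersecting that seed and with the seed itself. Seed members absent
    from the level's protein universe are ignored with a warning. If two
    seeds end up forced into one group they are merged with a warning and
    both origins recorded.
    """
    groups: list[tuple[set[str], set[str]]] = [
        (set(og.members), set(og.seed_origin)) for og in ogset.groups
    ]
    unclustered = set(ogset.unclustered)

    for seed in sorted(seeds, key=lambda s: s.id):
        members = set(seed.members)
        if universe is not None:
            unknown = members - universe
            if unknown:
                log.warning(
                    "seed %s: ignoring %d members absent from level %s",
                    seed.id, len(unknown), ogset.level,
                )
                members -= unknown
        if not members:
            continue
        hit_idx = [i for i, (mem, _) in enumerate(groups) if mem & members]
        new_members = set(members)
        new_origins = {seed.id}
        for i in hit_idx:
            new_members |= groups[i][0]
            new_origins |= groups[i][1]
        if len(new_origins) > 1:
            log.warning(
                "seeds %s forced into one OG at level %s",
                sorted(new_origins), ogset.level,
            )
        for i in reversed(hit_idx):
            del groups[i]
        unclustered -= new_members
        groups.append((new_members, new_origins))

    out = OGSet(level=ogset.level, unclustered=sorted(unclustered))
    for i, (members, origins) in enumerate(sorted(groups, key=lambda t: min(t[0]))):
        out.groups.append(
            OG(
                id=_base36(i),
                level=ogset.level,
                members=members,
                seed_origin=tuple(sorted(origins)),
            )
        )
    out.assert_disjoint()
    return out


# ---------------------------------------------------------------------------
# orchestration


def build_ogs(
    g: HitGraph,
    level: TaxLevel,
    seeds: Iterable[OG] = (),
) -> OGSet:
    """Full per-level clustering: in-paralogs → BBH → triangles → seeds.

    Deterministic for fixed input: unit ids, cluster merge order and OG id
    assignment are all derived from sorted protein/unit ids.
    """
    g = g.restrict_to_level(level)
    units = detect_inparalogs(g, level)
    bbh = unit_best_hits(units, g)
    ogset = triangle_merge(bbh, units, level)
    ogset = extend_seeds(ogset, seeds, universe=set(g.proteins))
    return ogset


# ---------------------------------------------------------------------------
# members-file round trip


def write_members(ogsets: Iterable[OGSet], stream: IO[str]) -> None:
    """Write OG membership as a TSV.

    Columns: level_id, og_id, n_members, n_species, comma-separated sorted
    member ids. One row per OG, levels in given order, OGs by id.
    """
    for ogset in ogsets:
        for og in sorted(ogset.groups, key=lambda o: o.id):
            members = sorted(og.members)
            stream.write(
                f"{og.level}\t{og.id}\t{len(members)}\t{len(og.species)}\t"
                f"{','.join(members)}\n"
            )


def read_members(stream: IO[str] | Iterable[str]) -> dict[str, OGSet]:
    """Read a members TSV back into per-level OGSets (keyed by level id)."""
    ogsets: dict[str, OGSet] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"line {lineno}: expected 5 columns, got {len(parts)}")
        level_id, og_id, n_members, _n_species, members_csv = parts
        members = {m for m in members_csv.split(",") if m}
        if len(members) != int(n_members):
            raise ValueError(
                f"line {lineno}: member count {len(members)} != declared {n_members}"
            )
        ogset = ogsets.setdefault(level_id, OGSet(level=level_id))
        ogset.groups.append(OG(id=og_id, level=level_id, members=members))
    for ogset in ogsets.values():
        ogset.assert_disjoint()
    return ogsets
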