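"""Hierarchical consistency of orthologous groups across nested levels.

Groups are clustered independently per taxonomic level, so a group at a
child level can straddle two groups at its parent level (a disagreement
about when a duplication happened). A post-clustering scan removes these
inconsistencies: levels are visited root-ward from the leaves; for every
child group divided at the parental level, the species overlap between
each pair of resulting partitions is examined in sequence from largest to
smallest. Pairs with no species in common are interpreted as an artificial
split — their parent groups are merged; pairs sharing species are a real
duplication — the smaller partition is separated out of the child group
(and out of every deeper level where the two still co-occur) into its own
group. The result: every group maps into exactly one group at its parent
level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

from .og_builder import OG, OGSet, _base36
from .simgraph import species_of
from .taxonomy import LevelHierarchy, TaxLevel

log = logging.getLogger(__name__)


class ConsistencyError(RuntimeError):
    pass


def species_overlap(a: Iterable[str], b: Iterable[str]) -> set[str]:
    """Species present in both protein-id sets."""
    return {species_of(p) for p in a} & {species_of(p) for p in b}


@dataclass
class SplitRecord:
    """A child OG whose members straddle ≥2 parent OGs.

    partitions holds the member sets grouped by parent OG, largest first
    (ties: fewer species last; equal there too → the partition containing
    the lexicographically smallest member id first). parent_ogs is the
    parallel list of parent OG ids. actions records what resolution did to
    each consecutive pair ("merged" or "separated").
    """

    child_og: str
    partitions: list[frozenset[str]]
    parent_ogs: list[str]
    actions: list[str] = field(default_factory=list)
    child_level: str = ""

    @property
    def resolution(self) -> str:
        return "separated" if "separated" in self.actions else "merged"


def _partition_sort_key(members: frozenset[str]) -> tuple:
    # larger first; ties: more species first; then smallest member id
    return (-len(members), -len({species_of(m) for m in members}), min(members))


def find_parental_splits(child: OGSet, parent: OGSet) -> list[SplitRecord]:
    """Detect child OGs divided at the parental level.

    Members unclustered at the parent level are excluded from partitions
    (and logged). Child OGs are scanned in id order.
    """
    parent_of = parent.membership()
    records: list[SplitRecord] = []
    for og in sorted(child.groups, key=lambda o: o.id):
        by_parent: dict[str, set[str]] = {}
        orphans = []
        for m in sorted(og.members):
            pid = parent_of.get(m)
            if pid is None:
                orphans.append(m)
            else:
                by_parent.setdefault(pid, set()).add(m)
        if orphans:
            log.debug(
                "OG %s/%s: %d members unclustered at parent level",
                child.level, og.id, len(orphans),
            )
        if len(by_parent) < 2:
            continue
        parts = sorted(
            ((frozenset(mem), pid) for pid, mem in by_parent.items()),
            key=lambda t: _partition_sort_key(t[0]),
        )
        records.append(
            SplitRecord(
                child_og=og.id,
                partitions=[p for p, _ in parts],
                parent_ogs=[pid for _, pid in parts],
            )
        )
    return records


@dataclass
class OGHierarchy:
    """Per-level OG sets tied to a level hierarchy."""

    hierarchy: LevelHierarchy
    ogsets: dict[str, OGSet]

    def __post_init__(self) -> None:
        for lid in self.ogsets:
            if lid not in self.hierarchy:
                raise ConsistencyError(f"OGSet for unknown level {lid!r}")

    def total_proteins(self) -> int:
        return sum(
            sum(len(og.members) for og in ogset.groups)
            for ogset in self.ogsets.values()
        )

    def check_nesting(self) -> list[str]:
        """Return violation messages; empty when hierarchically consistent.

        A violation is a non-root-level OG whose members (those clustered
        at the parent level at all) land in more than one parent OG.
        """
        violations = []
        for lid, ogset in self.ogsets.items():
            parent_id = self.hierarchy[lid].parent
            if parent_id is None or parent_id not in self.ogsets:
                continue
            parent_of = self.ogsets[parent_id].membership()
            for og in ogset.groups:
                parents = {parent_of[m] for m in og.members if m in parent_of}
                if len(parents) > 1:
                    violations.append(
                        f"{lid}/{og.id} straddles parent OGs {sorted(parents)}"
                    )
        return violations

    def is_consistent(self) -> bool:
        return not self.check_nesting()


def _fresh_id(ogset: OGSet) -> str:
    used = max((int(og.id, 36) for og in ogset.groups), default=-1)
    return _base36(used + 1)


def _get_og(ogset: OGSet, og_id: str) -> OG | None:
    for og in ogset.groups:
        if og.id == og_id:
            return og
    return None


def _separate(
    og_hier: OGHierarchy,
    child_level: TaxLevel,
    smaller: set[str],
    larger: set[str],
) -> None:
    """Pull the smaller partition out into its own OG at child_level and
    at every level below it where the two partitions still share an OG."""
    affected = [child_level] + og_hier.hierarchy.descendants(child_level.id)
    for lv in affected:
        ogset = og_hier.ogsets.get(lv.id)
        if ogset is None:
            continue
        for og in list(ogset.groups):
            small_in = og.members & smaller
            if small_in and og.members & larger:
                og.members -= small_in
                new = OG(
                    id=_fresh_id(ogset),
                    level=lv.id,
                    members=set(small_in),
                    seed_origin=og.seed_origin,
                )
                ogset.groups.append(new)
                if not og.members:  # cannot happen: larger side non-empty
                    ogset.groups.remove(og)


def resolve_split(
    rec: SplitRecord,
    og_hier: OGHierarchy,
    child_level: TaxLevel,
) -> OGHierarchy:
    """Resolve one split record in place (and return the hierarchy).

    Partitions are examined as consecutive pairs from largest to smallest,
    the surviving (merged or larger) partition carried forward. Empty
    species overlap → the two parent OGs are merged (full OGs, keeping the
    smaller id). Non-empty overlap → the smaller partition is separated at
    the child level and below.
    """
    parent_id = og_hier.hierarchy[child_level.id].parent
    assert parent_id is not None
    parent_set = og_hier.ogsets[parent_id]

    cur_members = set(rec.partitions[0])
    cur_parent = rec.parent_ogs[0]
    for nxt_members, nxt_parent in zip(rec.partitions[1:], rec.parent_ogs[1:]):
        nxt_members = set(nxt_members)
        if not species_overlap(cur_members, nxt_members):
            a = _get_og(parent_set, cur_parent)
            b = _get_og(parent_set, nxt_parent)
            if a is not None and b is not None and a is not b:
                keep, drop = (a, b) if int(a.id, 36) <= int(b.id, 36) else (b, a)
                keep.members |= drop.members
                keep.seed_origin = tuple(
                    sorted(set(keep.seed_origin) | set(drop.seed_origin))
                )
                parent_set.groups.remove(drop)
                cur_parent = keep.id
            cur_members |= nxt_members
            rec.actions.append("merged")
        else:
            pair = sorted(
                [(cur_members, cur_parent), (nxt_members, nxt_parent)],
                key=lambda t: _partition_sort_key(frozenset(t[0])),
            )
            (larger, larger_parent), (smaller, _) = pair
            _separate(og_hier, child_level, set(smaller), set(larger))
            cur_members, cur_parent = set(larger), larger_parent
            rec.actions.append("separated")
    return og_hier


def enforce_consistency(
    og_hier: OGHierarchy,
    report: list[SplitRecord] | None = None,
) -> OGHierarchy:
    """Scan levels root-ward from the leaves, resolving every split.

    At each non-root level the find/resolve cycle iterates to a fixed
    point; the whole sweep repeats until no level reports a record. A
    termination guard (more resolutions than clustered proteins at a
    level, or more sweeps than levels + 2) aborts with a diagnostic.
    Modifies ``og_hier`` in place and returns it. Resolved records are
    appended to ``report`` when given.
    """
    order = og_hier.hierarchy.leafward_order()
    guard = max(og_hier.total_proteins(), 1)
    for sweep in range(len(order) + 2):
        n_resolved = 0
        for lv in order:
            parent_id = lv.parent
            if parent_id is None:
                continue
            if lv.id not in og_hier.ogsets or parent_id not in og_hier.ogsets:
                continue
            for _ in range(guard + 1):
                records = find_parental_splits(
                    og_hier.ogsets[lv.id], og_hier.ogsets[parent_id]
                )
                if not records:
                    break
                # resolve one record, then rescan: resolutions can change
                # both levels, invalidating later records of this scan
                rec = records[0]
                rec.child_level = lv.id
                resolve_split(rec, og_hier, lv)
                if report is not None:
                    report.append(rec)
                n_resolved += 1
            else:
                raise ConsistencyError(
                    f"level {lv.id}: no fixed point after {guard + 1} resolutions"
                )
        if n_resolved == 0:
            violations = og_hier.check_nesting()
            if violations:
                raise ConsistencyError(
                    "nesting invariant violated after enforcement: "
                    + "; ".join(violations[:5])
                )
            return og_hier
    raise ConsistencyError("consistency sweeps did not converge")


def write_report(records: Iterable[SplitRecord], stream: IO[str]) -> None:
    """Audit TSV: child_level, child_og, resolution, partition sizes, overlap size."""
    for rec in records:
        sizes = ",".join(str(len(p)) for p in rec.partitions)
        overlap = len(species_overlap(rec.partitions[0], rec.partitions[1]))
        stream.write(
            f"{rec.child_level}\t{rec.child_og}\t{rec.resolution}\t{sizes}\t{overlap}\n"
        )
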