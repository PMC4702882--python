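"""Nested taxonomic levels at which orthologous groups are computed.

Orthologous groups are inferred independently at a set of manually chosen
taxonomic levels (clades), each owning the set of species it spans. The
levels form a rooted tree — e.g. LUCA at the root, with progressively
narrower clades (Eukaryota, Mammalia, Rodentia, ...) towards the tips —
and every child level's species set must be contained in its parent's.
This module represents that hierarchy and validates it on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable


class HierarchyError(ValueError):
    """Raised when a level table violates the hierarchy invariants."""


@dataclass(frozen=True)
class Species:
    """A genome/proteome participating in clustering.

    id is a short unique token (conventionally the numeric taxon id as
    text, e.g. "9606"); name is free text.
    """

    id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("species id must be non-empty")


@dataclass
class TaxLevel:
    """One clade at which clustering is run.

    species is the set of species ids whose proteins participate at this
    level. parent is the id of the enclosing level, or None for the root.
    """

    id: str
    name: str = ""
    parent: str | None = None
    species: set[str] = field(default_factory=set)


class LevelHierarchy:
    """A rooted tree of taxonomic levels with nested species sets.

    Invariants (enforced on construction):

    * exactly one root level (parent is None);
    * parent links form a tree (no cycles, no dangling parents);
    * every non-root level's species set is a subset of its parent's;
    * every species set is non-empty.
    """

    def __init__(self, levels: Iterable[TaxLevel]):
        self.levels: dict[str, TaxLevel] = {}
        for lv in levels:
            if lv.id in self.levels:
                raise HierarchyError(f"duplicate level id {lv.id!r}")
            self.levels[lv.id] = lv
        self._validate()

    # -- construction / validation ------------------------------------

    def _validate(self) -> None:
        roots = [lv.id for lv in self.levels.values() if lv.parent is None]
        if not self.levels:
            raise HierarchyError("hierarchy has no levels")
        if len(roots) != 1:
            raise HierarchyError(
                f"expected exactly one root level, found {len(roots)}: {sorted(roots)}"
            )
        self.root: str = roots[0]
        for lv in self.levels.values():
            if not lv.species:
                raise HierarchyError(f"level {lv.id!r} has an empty species set")
            if lv.parent is not None:
                if lv.parent not in self.levels:
                    raise HierarchyError(
                        f"level {lv.id!r} references unknown parent {lv.parent!r}"
                    )
                missing = lv.species - self.levels[lv.parent].species
                if missing:
                    raise HierarchyError(
                        f"species-subset violation: level {lv.id!r} lists species "
                        f"{sorted(missing)} absent from parent {lv.parent!r}"
                    )
        # cycle check: walk each level to the root
        for lv in self.levels.values():
            seen = {lv.id}
            cur = lv.parent
            while cur is not None:
                if cur in seen:
                    raise HierarchyError(f"cycle detected through level {cur!r}")
                seen.add(cur)
                cur = self.levels[cur].parent

    # -- queries --------------------------------------------------------

    def __contains__(self, level_id: str) -> bool:
        return level_id in self.levels

    def __getitem__(self, level_id: str) -> TaxLevel:
        return self.levels[level_id]

    def __len__(self) -> int:
        return len(self.levels)

    def children(self, level_id: str) -> list[TaxLevel]:
        """Direct child levels, sorted by id."""
        return sorted(
            (lv for lv in self.levels.values() if lv.parent == level_id),
            key=lambda lv: lv.id,
        )

    def descendants(self, level_id: str) -> list[TaxLevel]:
        """All strict descendants of a level, in breadth-first id-sorted order."""
        out: list[TaxLevel] = []
        frontier = self.children(level_id)
        while frontier:
            out.extend(frontier)
            frontier = [c for lv in frontier for c in self.children(lv.id)]
        return out

    def leafward_order(self) -> list[TaxLevel]:
        """Deterministic order in which every level precedes its parent.

        This is the root-ward scanning order used by the consistency pass:
        leaves first, root last. Ties among siblings (and more generally
        among levels at equal residual depth) are broken lexicographically
        by level id.
        """
        remaining = dict(self.levels)
        n_children = {lid: len(self.children(lid)) for lid in remaining}
        ready = sorted(lid for lid, n in n_children.items() if n == 0)
        order: list[TaxLevel] = []
        while ready:
            lid = ready.pop(0)
            lv = remaining.pop(lid)
            order.append(lv)
            if lv.parent is not None:
                n_children[lv.parent] -= 1
                if n_children[lv.parent] == 0:
                    # keep the ready list sorted for determinism
                    ready.append(lv.parent)
                    ready.sort()
        assert not remaining, "leafward_order failed to consume all levels"
        return order


def leafward_order(h: LevelHierarchy) -> list[TaxLevel]:
    """Module-level convenience wrapper for :meth:`LevelHierarchy.leafward_order`."""
    return h.leafward_order()


def load_hierarchy(stream: IO[str] | Iterable[str]) -> LevelHierarchy:
    """Parse a level-definition table into a validated hierarchy.

    The table is tab-separated with three columns: level id, parent id
    (blank for the root) and a comma-separated list of species ids.
    Lines starting with ``#`` and blank lines are ignored.
    """
    levels: list[TaxLevel] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise HierarchyError(
                f"line {lineno}: expected 3 tab-separated columns, got {len(parts)}"
            )
        level_id, parent_id, species_csv = (p.strip() for p in parts)
        if not level_id:
            raise HierarchyError(f"line {lineno}: empty level id")
        species = {s.strip() for s in species_csv.split(",") if s.strip()}
        levels.append(
            TaxLevel(
                id=level_id,
                parent=parent_id or None,
                species=species,
            )
        )
    return LevelHierarchy(levels)


def write_hierarchy(h: LevelHierarchy, stream: IO[str]) -> None:
    """Write the level table in the same format read by :func:`load_hierarchy`.

    Levels are emitted root-first (reverse leafward order) with sorted
    species lists, so write∘read∘write is byte-stable.
    """
    for lv in reversed(h.leafward_order()):
        stream.write(
            f"{lv.id}\t{lv.parent or ''}\t{','.join(sorted(lv.species))}\n"
        )
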