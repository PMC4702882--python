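"""Functional annotation of orthologous groups.

Per-protein annotations (free-text descriptions, GO/KEGG/SMART/PFAM terms,
domain architectures) are summarized per group: a consensus description is
distilled as the most descriptive shared word n-gram among annotated
members; term frequencies are computed relative to the members annotated
in each namespace; groups lacking a description inherit one from the
nearest annotated ancestor group in the level hierarchy, with an explicit
``inherited`` flag so downstream users can exclude such transfers. Two
viral-specific steps are included: merging groups that share a majority
Pfam clan-level domain architecture, and in-silico cleavage of polyproteins
into their mature chains.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from .consistency import OGHierarchy
from .og_builder import OG, OGSet, _base36

log = logging.getLogger(__name__)

NAMESPACES = ("GO", "KEGG", "SMART", "PFAM")

#: words carrying no functional signal, excluded from consensus building
STOP_WORDS = frozenset(
    {
        "protein", "putative", "hypothetical", "uncharacterized",
        "predicted", "conserved",
        # plus generic English glue
        "of", "the", "and", "with", "in", "to", "a", "an", "by", "for",
    }
)

_ACCESSION_RE = re.compile(r"^[a-z]{0,5}\d[\w.:-]*$")


@dataclass
class ProteinAnnotation:
    protein: str
    description: str = ""
    terms: set[tuple[str, str]] = field(default_factory=set)  # (namespace, term)
    domain_architecture: tuple[str, ...] = ()  # ordered clan ids

    def __post_init__(self) -> None:
        bad = {ns for ns, _ in self.terms} - set(NAMESPACES)
        if bad:
            raise ValueError(f"unknown namespaces {sorted(bad)}")


@dataclass
class OGAnnotation:
    og: str
    description: str = ""
    inherited: bool = False
    cog_category: set[str] = field(default_factory=set)
    term_frequencies: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class ChainAnnotation:
    """Mature-peptide coordinates on a polyprotein (1-based inclusive)."""

    polyprotein: str
    chains: list[tuple[int, int]]


# ---------------------------------------------------------------------------
# consensus description


def _tokenize(description: str) -> list[str]:
    """Lowercase word tokens, punctuation-stripped, stop/number/accession-free."""
    out = []
    for raw in description.lower().split():
        tok = raw.strip(".,;:()[]{}'\"!?/")
        if not tok or tok in STOP_WORDS:
            continue
        if tok.replace(".", "").isdigit():
            continue
        if _ACCESSION_RE.match(tok):
            continue
        out.append(tok)
    return out


def consensus_description(descriptions: Sequence[str]) -> str:
    """Most descriptive shared description substring among members.

    Empty descriptions are ignored. With a single (non-empty) input, that
    description is returned verbatim. Otherwise the winner is the word
    n-gram (over stop-word-filtered tokens) occurring in the greatest
    number of descriptions, with ties broken by n-gram length, then total
    character length, then lexicographically; n-grams covering fewer than
    2 descriptions do not qualify, so the result is "" when nothing is
    shared.
    """
    docs = [d for d in descriptions if d and d.strip()]
    if not docs:
        return ""
    if len(docs) == 1:
        return docs[0]

    coverage: dict[tuple[str, ...], int] = {}
    for doc in docs:
        toks = _tokenize(doc)
        grams = {
            tuple(toks[i:i + n])
            for n in range(1, len(toks) + 1)
            for i in range(len(toks) - n + 1)
        }
        for gram in grams:
            coverage[gram] = coverage.get(gram, 0) + 1

    candidates = [(c, g) for g, c in coverage.items() if c >= 2]
    if not candidates:
        return ""
    best = max(
        candidates,
        key=lambda t: (t[0], len(t[1]), len(" ".join(t[1])),
                       [-ord(ch) for ch in " ".join(t[1])]),
    )
    return " ".join(best[1])


# ---------------------------------------------------------------------------
# functional profiles


def functional_profile(
    og: OG, annos: Iterable[ProteinAnnotation]
) -> dict[tuple[str, str], float]:
    """Relative term frequencies within a group, per namespace.

    The denominator is the number of member proteins carrying at least one
    term in that namespace (not the full membership), so frequencies stay
    comparable between well- and sparsely-annotated groups. Empty when no
    member is annotated.
    """
    member_annos = [a for a in annos if a.protein in og.members]
    freqs: dict[tuple[str, str], float] = {}
    for ns in NAMESPACES:
        annotated = [a for a in member_annos if any(n == ns for n, _ in a.terms)]
        if not annotated:
            continue
        counts: dict[tuple[str, str], int] = {}
        for a in annotated:
            for key in {t for t in a.terms if t[0] == ns}:
                counts[key] = counts.get(key, 0) + 1
        for key, c in counts.items():
            freqs[key] = c / len(annotated)
    return freqs


# ---------------------------------------------------------------------------
# propagation across the hierarchy


def _parent_og_of(og: OG, parent_set: OGSet) -> OG | None:
    """The parent-level OG containing this OG's members (unique when the
    hierarchy is consistent); None if no member is clustered at the parent."""
    parent_of = parent_set.membership()
    hits = {parent_of[m] for m in og.members if m in parent_of}
    if not hits:
        return None
    assert len(hits) == 1, f"OG {og.id} straddles parent OGs {sorted(hits)}"
    (pid,) = hits
    return next(o for o in parent_set.groups if o.id == pid)


def propagate_annotations(
    og_hier: OGHierarchy,
    annos: dict[tuple[str, str], OGAnnotation],
) -> dict[tuple[str, str], OGAnnotation]:
    """Let unannotated groups inherit from their nearest annotated ancestor.

    ``annos`` maps (level id, og id) → annotation. Every OG with an empty
    description whose nearest annotated ancestor OG (following member
    containment up the level hierarchy) has one receives that ancestor's
    description and COG categories with ``inherited=True``. Requires a
    consistent hierarchy. Returns an updated copy of the map.
    """
    violations = og_hier.check_nesting()
    if violations:
        raise ValueError(
            "cannot propagate over an inconsistent hierarchy: "
            + "; ".join(violations[:3])
        )
    out = dict(annos)
    # leaf-ward levels inherit from root-ward ones: process root-first so a
    # chain of unannotated ancestors still resolves to the nearest annotated
    for lv in reversed(og_hier.hierarchy.leafward_order()):
        ogset = og_hier.ogsets.get(lv.id)
        if ogset is None or lv.parent is None:
            continue
        parent_set = og_hier.ogsets.get(lv.parent)
        if parent_set is None:
            continue
        for og in ogset.groups:
            key = (lv.id, og.id)
            cur = out.get(key, OGAnnotation(og=og.id))
            if cur.description:
                continue
            parent_og = _parent_og_of(og, parent_set)
            if parent_og is None:
                continue
            parent_anno = out.get((lv.parent, parent_og.id))
            if parent_anno is None or not parent_anno.description:
                continue
            out[key] = OGAnnotation(
                og=og.id,
                description=parent_anno.description,
                inherited=True,
                cog_category=set(parent_anno.cog_category),
                term_frequencies=dict(cur.term_frequencies),
            )
    return out


# ---------------------------------------------------------------------------
# viral clan-architecture merge


def majority_architecture(
    og: OG, annos: Iterable[ProteinAnnotation]
) -> tuple[str, ...] | None:
    """Domain architecture (clan-id sequence) held by a strict majority of
    the members that have a non-empty architecture; None if no majority."""
    archs = [
        a.domain_architecture
        for a in annos
        if a.protein in og.members and a.domain_architecture
    ]
    if not archs:
        return None
    counts: dict[tuple[str, ...], int] = {}
    for arch in archs:
        counts[arch] = counts.get(arch, 0) + 1
    arch, n = max(counts.items(), key=lambda t: (t[1], t[0]))
    return arch if n * 2 > len(archs) else None


def merge_by_clan_architecture(
    ogset: OGSet, annos: Sequence[ProteinAnnotation]
) -> OGSet:
    """Merge groups sharing an identical majority clan-level architecture.

    Architectures are compared order-sensitively. Groups without a strict
    majority architecture are left untouched.
    """
    by_arch: dict[tuple[str, ...], list[OG]] = {}
    untouched: list[OG] = []
    for og in sorted(ogset.groups, key=lambda o: o.id):
        arch = majority_architecture(og, annos)
        if arch is None:
            untouched.append(og)
        else:
            by_arch.setdefault(arch, []).append(og)

    merged_groups: list[tuple[set[str], tuple[str, ...]]] = []
    for arch in sorted(by_arch):
        ogs = by_arch[arch]
        members = set().union(*(og.members for og in ogs))
        origins = tuple(sorted({o for og in ogs for o in og.seed_origin}))
        merged_groups.append((members, origins))
    for og in untouched:
        merged_groups.append((set(og.members), tuple(og.seed_origin)))

    out = OGSet(level=ogset.level, unclustered=list(ogset.unclustered))
    for i, (members, origins) in enumerate(
        sorted(merged_groups, key=lambda t: min(t[0]))
    ):
        out.groups.append(
            OG(id=_base36(i), level=ogset.level, members=members,
               seed_origin=origins)
        )
    out.assert_disjoint()
    return out


# ---------------------------------------------------------------------------
# polyprotein cleavage


def cleave_polyprotein(
    sequence: str, chains: ChainAnnotation
) -> list[tuple[str, str]]:
    """Cleave a polyprotein into its mature chains, keeping smallest units.

    Coordinates are 1-based inclusive. A chain whose interval strictly
    contains another listed chain is discarded (only the smallest units
    are retained); identical extracted subsequences are deduplicated.
    Returns (chain id, subsequence) pairs; ids are
    ``<polyprotein>_<start>-<end>``.
    """
    for start, end in chains.chains:
        if not (1 <= start <= end <= len(sequence)):
            raise ValueError(
                f"chain ({start},{end}) out of range for sequence of "
                f"length {len(sequence)}"
            )
    kept = []
    for start, end in chains.chains:
        contains_other = any(
            (start <= s and e <= end) and (s, e) != (start, end)
            for s, e in chains.chains
        )
        if not contains_other:
            kept.append((start, end))
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for start, end in sorted(set(kept)):
        sub = sequence[start - 1:end]
        if sub in seen:
            continue
        seen.add(sub)
        out.append((f"{chains.polyprotein}_{start}-{end}", sub))
    return out


# ---------------------------------------------------------------------------
# annotation table I/O


def read_protein_annotations(
    stream: IO[str] | Iterable[str],
) -> list[ProteinAnnotation]:
    """Read the 7-column annotation TSV.

    Columns: protein_id, description, GO_csv, KEGG_csv, SMART_csv,
    PFAM_csv, clan_architecture_csv.
    """
    out = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        pid, desc, go, kegg, smart, pfam, arch = parts
        terms = set()
        for ns, csv in zip(NAMESPACES, (go, kegg, smart, pfam)):
            terms.update((ns, t) for t in csv.split(",") if t)
        out.append(
            ProteinAnnotation(
                protein=pid,
                description=desc,
                terms=terms,
                domain_architecture=tuple(t for t in arch.split(",") if t),
            )
        )
    return out


def write_protein_annotations(
    annos: Iterable[ProteinAnnotation], stream: IO[str]
) -> None:
    for a in annos:
        cols = [a.protein, a.description]
        for ns in NAMESPACES:
            cols.append(",".join(sorted(t for n, t in a.terms if n == ns)))
        cols.append(",".join(a.domain_architecture))
        stream.write("\t".join(cols) + "\n")


def write_og_annotations(
    rows: Iterable[tuple[str, OGAnnotation]], stream: IO[str]
) -> None:
    """OG annotation TSV: level_id, og_id, cog_categories, description, inherited."""
    for level_id, anno in rows:
        stream.write(
            f"{level_id}\t{anno.og}\t{''.join(sorted(anno.cog_category))}\t"
            f"{anno.description}\t{int(anno.inherited)}\n"
        )


def write_term_frequencies(
    rows: Iterable[tuple[str, OGAnnotation]], stream: IO[str]
) -> None:
    """Per-namespace frequency TSV: level_id, og_id, namespace, term, frequency."""
    for level_id, anno in rows:
        for (ns, term), f in sorted(anno.term_frequencies.items()):
            stream.write(f"{level_id}\t{anno.og}\t{ns}\t{term}\t{f:g}\n")
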