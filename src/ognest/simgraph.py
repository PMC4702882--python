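"""All-vs-all protein similarity graph: parsing, filtering, indexing.

The clustering stage consumes an all-against-all similarity matrix of
Smith–Waterman bit-scores computed upstream. Hits are read from a 3-column
TSV (query, subject, bitscore), filtered at a bit-score threshold (default:
strictly greater than 50 bits), symmetrized into an undirected weighted
graph, and restricted to the species of a taxonomic level before group
building.

Protein identifiers carry their species as a prefix delimited by the first
'.', e.g. ``9606.ENSP00000263025``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import networkx as nx

from .taxonomy import TaxLevel

log = logging.getLogger(__name__)

#: Default bit-score cutoff: hits at or below this many bits are discarded.
DEFAULT_BITSCORE_THRESHOLD = 50.0


class HitParseError(ValueError):
    pass


def species_of(protein_id: str) -> str:
    """Species token of a protein id (prefix before the first '.')."""
    sp, sep, rest = protein_id.partition(".")
    if not sep or not sp or not rest:
        raise HitParseError(
            f"protein id {protein_id!r} lacks a 'species.protein' prefix"
        )
    return sp


@dataclass(frozen=True)
class Hit:
    """One directed similarity hit (query → subject, bit-score in bits)."""

    query: str
    subject: str
    bitscore: float

    def __post_init__(self) -> None:
        if self.query == self.subject:
            raise HitParseError(f"self-hit {self.query!r} rejected")
        if self.bitscore < 0:
            raise HitParseError(f"negative bitscore {self.bitscore}")
        # validate species prefixes eagerly
        species_of(self.query)
        species_of(self.subject)


def parse_hits(
    stream: IO[str] | Iterable[str],
    *,
    strict: bool = False,
) -> list[Hit]:
    """Parse a hit table, reporting malformed lines with their numbers.

    Each line: ``query<TAB>subject<TAB>bitscore``. Malformed lines (bad
    column count, unparseable score, missing species prefix, self-hits)
    are logged with line numbers and skipped; with ``strict=True`` the
    first one raises instead.
    """
    hits: list[Hit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            parts = line.split("\t")
            if len(parts) != 3:
                raise HitParseError(
                    f"expected 3 tab-separated columns, got {len(parts)}"
                )
            q, s, score_txt = parts
            try:
                score = float(score_txt)
            except ValueError:
                raise HitParseError(f"unparseable bitscore {score_txt!r}") from None
            hits.append(Hit(q.strip(), s.strip(), score))
        except HitParseError as exc:
            if strict:
                raise HitParseError(f"line {lineno}: {exc}") from None
            log.warning("skipping malformed hit line %d: %s", lineno, exc)
    return hits


def iter_hit_file(path: str | Path, **kwargs) -> list[Hit]:
    """Parse hits from a plain or gzip-compressed TSV file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8") as fh:  # type: ignore[operator]
        return parse_hits(fh, **kwargs)


def filter_hits(
    hits: Iterable[Hit], threshold: float = DEFAULT_BITSCORE_THRESHOLD
) -> list[Hit]:
    """Keep hits with bit-score strictly greater than ``threshold``.

    A hit at exactly the threshold (e.g. 50.0 bits at the default) is
    dropped; 50.0 + ε is kept. Idempotent.
    """
    return [h for h in hits if h.bitscore > threshold]


def symmetrize(hits: Iterable[Hit]) -> "HitGraph":
    """Collapse directed hits into an undirected weighted graph.

    When both directions of a pair were observed (possibly with different
    scores, as alignment scores need not be exactly symmetric), the edge
    weight is the maximum of the two; a pair seen in one direction keeps
    that score.
    """
    g = HitGraph()
    for h in hits:
        g.add_protein(h.query)
        g.add_protein(h.subject)
        prev = g.graph.edges.get((h.query, h.subject))
        if prev is None or h.bitscore > prev["weight"]:
            g.graph.add_edge(h.query, h.subject, weight=h.bitscore)
    return g


class HitGraph:
    """Undirected weighted graph of filtered, symmetrized similarity hits.

    Nodes are protein ids with species attribution; edges carry the
    symmetrized bit-score as ``weight``. Backed by a networkx Graph.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    def add_protein(self, protein_id: str) -> None:
        self.graph.add_node(protein_id, species=species_of(protein_id))

    # -- queries --------------------------------------------------------

    @property
    def proteins(self) -> list[str]:
        return sorted(self.graph.nodes)

    def species(self, protein_id: str) -> str:
        return self.graph.nodes[protein_id]["species"]

    def score(self, a: str, b: str) -> float:
        """Symmetrized score of a pair, 0.0 if no edge."""
        data = self.graph.edges.get((a, b))
        return 0.0 if data is None else data["weight"]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        for a, b, w in self.graph.edges.data("weight"):
            yield a, b, w

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def restrict_to_level(self, level: TaxLevel) -> "HitGraph":
        """Induced subgraph on proteins whose species belong to the level."""
        keep = [
            n
            for n, sp in self.graph.nodes(data="species")
            if sp in level.species
        ]
        return HitGraph(self.graph.subgraph(keep).copy())


def restrict_to_level(g: HitGraph, level: TaxLevel) -> HitGraph:
    """Module-level convenience wrapper for :meth:`HitGraph.restrict_to_level`."""
    return g.restrict_to_level(level)


def write_hits(hits: Iterable[Hit], stream: IO[str]) -> None:
    """Write hits as a 3-column TSV (the format read by :func:`parse_hits`)."""
    for h in hits:
        stream.write(f"{h.query}\t{h.subject}\t{h.bitscore:g}\n")
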