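"""Ranked taxonomic lineages: parsing, membership, span and overlap.

Every sequence in the pipeline carries a :class:`Lineage` — an ordered list of
taxon names from root to tip, each tagged with one of the eight canonical
ranks (superkingdom down to species).  Real reference lineages are ragged, so
a lineage may *skip* ranks (bacterial lineages frequently lack a ``kingdom``
entry); comparisons always operate on ``(rank, name)`` pairs so a skipped rank
never aligns against a present one.

Three comparison primitives drive the downstream stages:

- :func:`is_member` — does a lineage contain a taxon name (e.g. "Fungi")?
- :func:`span_rank` — the most rootward rank at which a set of lineages
  disagrees; quantifies how taxonomically wide a group of sequences is.
- :func:`lineage_overlap` — fraction of the query's lineage shared as a root
  prefix with another lineage; the distance kernel inside the LPI screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

#: The fixed rank hierarchy, most rootward first.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}


def rank_index(rank: str) -> int:
    """Position of *rank* in the hierarchy (0 = superkingdom, 7 = species)."""
    try:
        return _RANK_INDEX[rank]
    except KeyError:
        raise ValueError(f"unknown rank label: {rank!r}") from None


def rank_at_or_rootward(rank: str, reference: str) -> bool:
    """True if *rank* is *reference* or closer to the root."""
    return rank_index(rank) <= rank_index(reference)


@dataclass(frozen=True)
class Lineage:
    """An ordered ranked lineage for one sequence, root to tip.

    Parameters
    ----------
    terms:
        Taxon names, most rootward first (e.g. ``("Eukaryota", "Fungi", ...)``).
    ranks:
        Parallel rank labels drawn from :data:`RANKS`, in hierarchy order and
        without repetition.  The first rank must be ``superkingdom``.
    """

    terms: tuple[str, ...]
    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("lineage must have at least one term")
        if len(self.terms) != len(self.ranks):
            raise ValueError(
                f"terms/ranks length mismatch: {len(self.terms)} != {len(self.ranks)}"
            )
        last = -1
        for rank in self.ranks:
            idx = rank_index(rank)
            if idx <= last:
                raise ValueError(
                    f"ranks out of hierarchy order or repeated at {rank!r}"
                )
            last = idx
        if self.ranks[0] != "superkingdom":
            raise ValueError(
                f"lineage must start at superkingdom, got {self.ranks[0]!r}"
            )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Lineage":
        """Build from an iterable of ``(rank, name)`` pairs."""
        pairs = tuple(pairs)
        return cls(
            terms=tuple(name for _, name in pairs),
            ranks=tuple(rank for rank, _ in pairs),
        )

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        """``(rank, name)`` pairs, root to tip."""
        return tuple(zip(self.ranks, self.terms))

    def name_at(self, rank: str) -> str | None:
        """Taxon name at *rank*, or None when the lineage skips that rank."""
        rank_index(rank)  # validate
        for r, name in zip(self.ranks, self.terms):
            if r == rank:
                return name
        return None

    @property
    def species(self) -> str | None:
        return self.name_at("species")

    def __len__(self) -> int:
        return len(self.terms)

    def to_field(self) -> str:
        """Serialize to the ``rank:name;rank:name`` TSV field format."""
        return ";".join(f"{r}:{n}" for r, n in self.pairs)

    @classmethod
    def from_field(cls, field: str) -> "Lineage":
        pairs = []
        for chunk in field.strip().split(";"):
            if not chunk:
                continue
            rank, sep, name = chunk.partition(":")
            if not sep or not name:
                raise ValueError(f"malformed rank:name chunk: {chunk!r}")
            pairs.append((rank.strip(), name.strip()))
        return cls.from_pairs(pairs)


class TaxonomyTable:
    """Mapping from sequence/species id to :class:`Lineage`, with unique ids."""

    def __init__(self, entries: Mapping[str, Lineage] | None = None) -> None:
        self._entries: dict[str, Lineage] = {}
        if entries:
            for key, lineage in entries.items():
                self.add(key, lineage)

    def add(self, key: str, lineage: Lineage) -> None:
        if key in self._entries:
            raise ValueError(f"duplicate id in taxonomy table: {key!r}")
        self._entries[key] = lineage

    def __getitem__(self, key: str) -> Lineage:
        try:
            return self._entries[key]
        except KeyError:
            raise KeyError(f"id not in taxonomy table: {key!r}") from None

    def get(self, key: str, default: Lineage | None = None) -> Lineage | None:
        return self._entries.get(key, default)

    def __contains__(self, key: str) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def items(self) -> Iterable[tuple[str, Lineage]]:
        return self._entries.items()

    def ids(self) -> list[str]:
        return list(self._entries)

    def merged_with(self, other: "TaxonomyTable") -> "TaxonomyTable":
        """New table with entries of both; duplicate ids must agree."""
        merged = TaxonomyTable(dict(self._entries))
        for key, lineage in other.items():
            existing = merged.get(key)
            if existing is None:
                merged.add(key, lineage)
            elif existing != lineage:
                raise ValueError(f"conflicting lineages for id {key!r}")
        return merged

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# id\tlineage (rank:name;...)\n")
            for key, lineage in self._entries.items():
                fh.write(f"{key}\t{lineage.to_field()}\n")


def parse_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy TSV (``<id>\\t<rank:name;...>``; ``#`` comments ignored)."""
    table = TaxonomyTable()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            try:
                key, field = line.split("\t", 1)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                ) from None
            try:
                lineage = Lineage.from_field(field)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            table.add(key.strip(), lineage)
    return table


def is_member(lineage: Lineage, taxon: str) -> bool:
    """True iff *taxon* appears among the lineage's terms (exact match)."""
    return bool(taxon) and taxon in lineage.terms


def span_rank(lineages: Iterable[Lineage]) -> str:
    """Most rootward rank at which the set disagrees, or ``"uniform"``.

    A set "disagrees" at a rank when its members name more than one taxon
    there, counting a skipped rank as a distinct value.  Identical lineages
    (down to species) return ``"uniform"``.
    """
    pool = list(lineages)
    if not pool:
        raise ValueError("span_rank of an empty lineage set")
    for rank in RANKS:
        names = {lin.name_at(rank) for lin in pool}
        if len(names) > 1:
            return rank
    return "uniform"


def lineage_overlap(a: Lineage, b: Lineage) -> float:
    """Shared root-prefix fraction of the query lineage *a*.

    The longest common root prefix of ``(rank, name)`` pairs is divided by the
    length of *a* — the measure is asymmetric and reads as "how much of the
    query's taxonomic annotation does *b* confirm".
    """
    shared = 0
    for pa, pb in zip(a.pairs, b.pairs):
        if pa != pb:
            break
        shared += 1
    return shared / len(a.terms)
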