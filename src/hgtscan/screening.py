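"""Candidate screening: hit filtering, a lineage probability index, dedup.

The screen flags proteins whose database homologs are taxonomically anomalous.
For each query protein with a table of BLAST-style hits we compute a lineage
probability index (LPI): the bitscore-weighted mean of
:func:`~hgtscan.taxonomy.lineage_overlap` between the query's lineage and each
eligible hit's lineage.  The LPI lives in [0, 1]; values near 1 mean the
strong hits come from taxonomic neighbours (vertical descent), values near 0
mean they come from distant lineages.  A query becomes an HGT candidate when
its LPI falls below a threshold (default 0.7) *and* its best eligible hit
lies outside the focal kingdom (default "Fungi").

The index is deliberately transparent: a bitscore-weighted mean overlap with
the documented eligibility rules (minimum alignment coverage, minimum lineage
term count, optional self-species exclusion).  It is monotone in the
taxonomic closeness of the hit set, which is the property the downstream
decision procedure relies on.

A separate, stricter filter (:func:`filter_hits`) restricts the homolog set
used for tree building: identity over 35%, query coverage above 65%, e-value
below 1e-5 — all strict inequalities.  :func:`dedupe_sequences` collapses
100%-identical sequences the way CD-HIT at a 1.0 threshold would, keeping a
collapse map so no taxonomic information is lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from hgtscan.taxonomy import Lineage, TaxonomyTable, is_member, lineage_overlap

__all__ = [
    "HomologHit",
    "ScreenConfig",
    "ScreenResult",
    "filter_hits",
    "eligible_hits",
    "compute_lpi",
    "screen_candidates",
    "dedupe_sequences",
    "read_fasta",
    "read_hits_tsv",
    "write_screen_results_tsv",
]

#: Column order of the BLAST outfmt-6-like hit table consumed by the screen.
HIT_COLUMNS = ("qseqid", "sseqid", "pident", "qcovhsp", "evalue", "bitscore", "staxon")


@dataclass(frozen=True)
class HomologHit:
    """One row of a BLAST-style tabular hit."""

    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    evalue: float
    bitscore: float
    subject_lineage: Lineage

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity out of [0,100]: {self.percent_identity}")
        if not 0.0 <= self.query_coverage <= 100.0:
            raise ValueError(f"query_coverage out of [0,100]: {self.query_coverage}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")
        if self.bitscore <= 0:
            raise ValueError(f"bitscore must be positive: {self.bitscore}")


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the LPI screen and the tree-building hit filter.

    ``lpi_threshold``, ``min_lineage_terms`` and ``min_coverage_lpi`` govern
    candidate flagging; the ``filter_*`` values govern which hits are kept as
    homologs for phylogenetic analysis.
    """

    lpi_threshold: float = 0.7
    min_lineage_terms: int = 3
    min_coverage_lpi: float = 0.7
    filter_min_identity: float = 35.0
    filter_min_coverage: float = 65.0
    filter_max_evalue: float = 1e-5
    exclude_self_species: bool = True
    focal_kingdom: str = "Fungi"

    def __post_init__(self) -> None:
        if not 0.0 < self.lpi_threshold <= 1.0:
            raise ValueError(f"lpi_threshold out of (0,1]: {self.lpi_threshold}")
        if self.min_lineage_terms < 1:
            raise ValueError("min_lineage_terms must be >= 1")
        if not 0.0 <= self.min_coverage_lpi <= 1.0:
            raise ValueError("min_coverage_lpi must be a fraction in [0,1]")
        if not 0.0 <= self.filter_min_identity <= 100.0:
            raise ValueError("filter_min_identity out of [0,100]")
        if not 0.0 <= self.filter_min_coverage <= 100.0:
            raise ValueError("filter_min_coverage out of [0,100]")
        if self.filter_max_evalue < 0:
            raise ValueError("filter_max_evalue must be non-negative")


@dataclass(frozen=True)
class ScreenResult:
    """Per-query outcome of the screen."""

    query_id: str
    lpi: float
    best_hit_taxon_nonfocal_kingdom: bool
    is_candidate: bool


def filter_hits(hits: Sequence[HomologHit], config: ScreenConfig | None = None) -> list[HomologHit]:
    """Keep hits usable as homologs for tree building.

    Strict bounds: identity > 35, coverage > 65, e-value < 1e-5 (defaults).
    Input order is preserved; the operation is idempotent.
    """
    cfg = config or ScreenConfig()
    return [
        h
        for h in hits
        if h.percent_identity > cfg.filter_min_identity
        and h.query_coverage > cfg.filter_min_coverage
        and h.evalue < cfg.filter_max_evalue
    ]


def eligible_hits(
    query_lineage: Lineage,
    hits: Sequence[HomologHit],
    config: ScreenConfig | None = None,
) -> list[HomologHit]:
    """Hits eligible for LPI computation and best-hit selection.

    Eligibility: alignment coverage at least ``min_coverage_lpi`` (as a
    percentage), at least ``min_lineage_terms`` lineage terms, and — when
    ``exclude_self_species`` — a subject species different from the query's
    (otherwise every query trivially scores near 1).
    """
    cfg = config or ScreenConfig()
    query_species = query_lineage.species
    out = []
    for h in hits:
        if h.query_coverage < cfg.min_coverage_lpi * 100.0:
            continue
        if len(h.subject_lineage) < cfg.min_lineage_terms:
            continue
        if (
            cfg.exclude_self_species
            and query_species is not None
            and h.subject_lineage.species == query_species
        ):
            continue
        out.append(h)
    return out


def compute_lpi(
    query_lineage: Lineage,
    hits: Sequence[HomologHit],
    config: ScreenConfig | None = None,
) -> float:
    """Bitscore-weighted mean lineage overlap of *hits* with the query.

    ``hits`` are assumed already restricted to eligible hits (see
    :func:`eligible_hits`); an empty hit list scores 0.
    """
    if not hits:
        return 0.0
    total = sum(h.bitscore for h in hits)
    weighted = sum(h.bitscore * lineage_overlap(query_lineage, h.subject_lineage) for h in hits)
    return weighted / total


def _best_hit(hits: Sequence[HomologHit]) -> HomologHit | None:
    """Top hit by bitscore; ties broken by lower e-value, then subject id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))


def screen_candidates(
    table: Mapping[str, tuple[Lineage, Sequence[HomologHit]]],
    config: ScreenConfig | None = None,
) -> list[ScreenResult]:
    """Run the LPI screen over a query → (lineage, hits) table.

    A query is flagged as a candidate iff its LPI is strictly below the
    threshold *and* the highest-bitscore eligible hit's lineage lacks the
    focal kingdom term.
    """
    cfg = config or ScreenConfig()
    results = []
    for query_id, (query_lineage, hits) in table.items():
        elig = eligible_hits(query_lineage, hits, cfg)
        lpi = compute_lpi(query_lineage, elig, cfg)
        best = _best_hit(elig)
        nonfocal = best is not None and not is_member(best.subject_lineage, cfg.focal_kingdom)
        results.append(
            ScreenResult(
                query_id=query_id,
                lpi=lpi,
                best_hit_taxon_nonfocal_kingdom=nonfocal,
                is_candidate=(lpi < cfg.lpi_threshold and nonfocal),
            )
        )
    return results


def dedupe_sequences(
    records: Iterable,
    focal_id: str | None = None,
) -> tuple[list, dict[str, str]]:
    """Collapse exact full-length duplicate sequences to one representative.

    *records* is any iterable of objects with ``.id`` and a sequence
    retrievable via ``str(record.seq)`` (Biopython ``SeqRecord``) or
    ``(id, sequence)`` tuples.  The first record of each duplicate class is
    the representative, except that a focal candidate always wins
    representative status for its class.  Returns the kept records (input
    order) and a map removed-id → representative-id; taxonomic annotations of
    removed ids remain reachable through the map.
    """

    def _id_seq(rec) -> tuple[str, str]:
        if isinstance(rec, tuple):
            return rec[0], str(rec[1])
        return rec.id, str(rec.seq)

    recs = list(records)
    ids_seen: set[str] = set()
    for rec in recs:
        rid, _ = _id_seq(rec)
        if rid in ids_seen:
            raise ValueError(f"duplicate record id: {rid!r}")
        ids_seen.add(rid)

    # representative per sequence string: focal wins, else first occurrence
    rep_for_seq: dict[str, str] = {}
    for rec in recs:
        rid, seq = _id_seq(rec)
        if seq not in rep_for_seq:
            rep_for_seq[seq] = rid
        elif rid == focal_id:
            rep_for_seq[seq] = rid

    kept = []
    collapse: dict[str, str] = {}
    for rec in recs:
        rid, seq = _id_seq(rec)
        if rep_for_seq[seq] == rid:
            kept.append(rec)
        else:
            collapse[rid] = rep_for_seq[seq]
    return kept, collapse


def read_fasta(path: str | Path) -> list:
    """Read FASTA records (Biopython ``SeqRecord`` objects, input order)."""
    return list(SeqIO.parse(str(path), "fasta"))


def read_hits_tsv(
    path: str | Path,
    taxonomy: TaxonomyTable,
) -> dict[str, list[HomologHit]]:
    """Read a BLAST outfmt-6-like hit table, resolving lineages via *taxonomy*.

    Columns: qseqid, sseqid, pident, qcovhsp, evalue, bitscore, staxon.
    ``staxon`` is a key into the taxonomy table.  Returns hits grouped by
    query id, input order preserved.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=HIT_COLUMNS, dtype=str)
    grouped: dict[str, list[HomologHit]] = {}
    for row in df.itertuples(index=False):
        lineage = taxonomy[row.staxon]
        hit = HomologHit(
            query_id=row.qseqid,
            subject_id=row.sseqid,
            percent_identity=float(row.pident),
            query_coverage=float(row.qcovhsp),
            evalue=float(row.evalue),
            bitscore=float(row.bitscore),
            subject_lineage=lineage,
        )
        grouped.setdefault(row.qseqid, []).append(hit)
    return grouped


def write_hits_tsv(path: str | Path, hits: Sequence[HomologHit], staxon_of: Mapping[str, str]) -> None:
    """Write hits in the outfmt-6-like layout; ``staxon_of`` maps subject id → taxon key."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:g}",
                        f"{h.query_coverage:g}",
                        f"{h.evalue:g}",
                        f"{h.bitscore:g}",
                        staxon_of[h.subject_id],
                    ]
                )
                + "\n"
            )


def write_screen_results_tsv(path: str | Path, results: Sequence[ScreenResult]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("query_id\tlpi\tbest_hit_nonfocal_kingdom\tis_candidate\n")
        for r in results:
            fh.write(
                f"{r.query_id}\t{r.lpi:.6f}\t{int(r.best_hit_taxon_nonfocal_kingdom)}\t{int(r.is_candidate)}\n"
            )
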