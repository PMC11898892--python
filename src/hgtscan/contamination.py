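"""Contig-context triage of candidates without fungal homologs.

A protein whose gene tree shows no fungal relatives is either a genuine
species-specific horizontal acquisition or a stretch of foreign DNA that was
co-assembled into the genome.  The two are distinguished by the genomic
neighbourhood: if every flanking feature on the candidate's contig has its
best database hit in a non-fungal kingdom, the whole contig is presumed
foreign and the candidate is excluded as contamination.  A single flanking
feature with a fungal best hit anchors the contig in the host genome and
clears the candidate.  A contig providing no informative flanks (no hits, or
the candidate alone on its contig) is *indeterminate*, which downstream
defaults to exclusion — the conservative reading.

The module consumes a prepared per-feature best-hit-kingdom table; it does
not run the flanking BLAST searches itself.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence


class Verdict(str, enum.Enum):
    CLEAN = "clean"
    CONTAMINATED = "contaminated"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ContigContext:
    """Ordered flanking features of one candidate gene on its contig.

    ``features`` is ordered by contig coordinate; each entry is
    ``(feature_id, best_hit_kingdom)`` where the kingdom is a taxon name or
    ``None`` when the feature had no database hit.  ``focal_index`` marks the
    candidate's own feature.
    """

    contig_id: str
    features: tuple[tuple[str, str | None], ...]
    focal_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.focal_index < len(self.features):
            raise ValueError(
                f"focal_index {self.focal_index} out of range for "
                f"{len(self.features)} features"
            )

    @property
    def flanking(self) -> tuple[tuple[str, str | None], ...]:
        return tuple(
            f for i, f in enumerate(self.features) if i != self.focal_index
        )


@dataclass(frozen=True)
class ContaminationVerdict:
    verdict: Verdict
    n_flanking_focal: int
    n_flanking_other: int


def assess_contamination(
    context: ContigContext, focal_kingdom: str = "Fungi"
) -> ContaminationVerdict:
    """Judge a contig by the kingdoms of its flanking features' best hits.

    - *contaminated*: at least one flank has a hit and every flank with a hit
      is non-focal-kingdom (the entire contig matches foreign sequence).
    - *clean*: at least one flank's best hit is in the focal kingdom.
    - *indeterminate*: no flanking feature has any hit.
    """
    kingdoms = [k for _, k in context.flanking if k is not None]
    n_focal = sum(1 for k in kingdoms if k == focal_kingdom)
    n_other = len(kingdoms) - n_focal
    if n_focal >= 1:
        verdict = Verdict.CLEAN
    elif n_other >= 1:
        verdict = Verdict.CONTAMINATED
    else:
        verdict = Verdict.INDETERMINATE
    return ContaminationVerdict(
        verdict=verdict, n_flanking_focal=n_focal, n_flanking_other=n_other
    )


def parse_contigs_tsv(path: str | Path) -> dict[str, ContigContext]:
    """Read contig contexts keyed by focal feature id.

    Columns: contig_id, feature_id, start, end, best_hit_kingdom, is_focal.
    ``best_hit_kingdom`` of ``none`` (case-insensitive) or empty means no hit.
    Features are sorted by start coordinate within each contig.
    """
    rows: dict[str, list[tuple[int, str, str | None, bool]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("contig_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            contig_id, feature_id, start, _end, kingdom, is_focal = parts
            k = None if kingdom.strip().lower() in ("", "none", "na") else kingdom.strip()
            rows.setdefault(contig_id, []).append(
                (int(start), feature_id, k, is_focal.strip() == "1")
            )
    contexts: dict[str, ContigContext] = {}
    for contig_id, feats in rows.items():
        feats.sort(key=lambda t: t[0])
        focal_idx = [i for i, f in enumerate(feats) if f[3]]
        if len(focal_idx) != 1:
            raise ValueError(
                f"contig {contig_id!r} must have exactly one focal feature, "
                f"found {len(focal_idx)}"
            )
        focal_feature_id = feats[focal_idx[0]][1]
        contexts[focal_feature_id] = ContigContext(
            contig_id=contig_id,
            features=tuple((fid, k) for _, fid, k, _ in feats),
            focal_index=focal_idx[0],
        )
    return contexts


def write_verdicts_tsv(
    path: str | Path, verdicts: dict[str, ContaminationVerdict]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("candidate_id\tverdict\tn_flanking_focal\tn_flanking_other\n")
        for cid, v in verdicts.items():
            fh.write(
                f"{cid}\t{v.verdict.value}\t{v.n_flanking_focal}\t{v.n_flanking_other}\n"
            )
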