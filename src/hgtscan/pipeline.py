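"""End-to-end orchestration: generate → classify → triage → finalize → report.

:func:`run_replication` drives a replication manifest through the whole
decision procedure and tallies the five final-call categories, reporting
percentages with half-up rounding to one decimal.  :func:`map_transfers`
places every accepted HGT call on the species tree at its minimum transfer
node (the MRCA of the receptor species).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from hgtscan.contamination import Verdict, assess_contamination
from hgtscan.synthetic import (
    ReplicationManifest,
    generate_contig,
    generate_taxonomy,
    generate_tree,
)
from hgtscan.taxonomy import TaxonomyTable
from hgtscan.tree_classify import (
    ClassifyConfig,
    FinalCall,
    PatternCall,
    SpeciesTree,
    TopologyPattern,
    classify_pattern,
    finalize_call,
    infer_transfer_node,
    node_label,
)

__all__ = [
    "RunReport",
    "run_replication",
    "map_transfers",
    "species_tree_from_taxonomy",
    "percent_half_up",
    "write_calls_tsv",
    "read_calls_tsv",
]

_FINAL_CALLS = tuple(fc.value for fc in FinalCall)


def percent_half_up(count: int, total: int) -> float:
    """``100*count/total`` rounded half-up to one decimal; 0.0 for empty totals."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class RunReport:
    """Per-candidate calls plus category counts and percentages."""

    name: str
    master_seed: int
    rows: tuple[PatternCall, ...]
    transfers: tuple[dict, ...] = ()

    @property
    def total(self) -> int:
        return len(self.rows)

    @property
    def counts(self) -> dict[str, int]:
        out = {fc: 0 for fc in _FINAL_CALLS}
        for row in self.rows:
            out[row.final_call.value] += 1
        return out

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total
        return {fc: percent_half_up(n, total) for fc, n in self.counts.items()}

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "master_seed": self.master_seed,
            "total": self.total,
            "counts": self.counts,
            "percentages": self.percentages,
            "calls": [_row_to_dict(r) for r in self.rows],
            "transfers": list(self.transfers),
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _row_to_dict(row: PatternCall) -> dict:
    return {
        "candidate_id": row.candidate_id,
        "topology_pattern": row.topology_pattern.value,
        "final_call": row.final_call.value if row.final_call else None,
        "focal_patch_size": len(row.focal_patch),
        "focal_patch": list(row.focal_patch),
        "focal_patch_span": row.focal_patch_span,
        "outside_fungal_count": row.outside_fungal_count,
        "donor_count": row.donor_count,
        "contamination_verdict": row.contamination.value if row.contamination else None,
    }


def run_replication(
    manifest: ReplicationManifest,
    config: ClassifyConfig | None = None,
    taxonomy: TaxonomyTable | None = None,
    indeterminate_is_clean: bool = False,
) -> RunReport:
    """Generate, classify, triage and finalize every scenario of a manifest.

    Deterministic for a given (manifest, config): each scenario's fixtures
    are generated from its own seed, classified, D-pattern cases are triaged
    against their planted contig context, and the final calls are tallied.
    Any stage error is re-raised with the candidate id attached.
    """
    cfg = config or ClassifyConfig()
    taxonomy = taxonomy or generate_taxonomy()
    rows: list[PatternCall] = []
    for spec in manifest.specs:
        try:
            tree = generate_tree(spec, taxonomy)
            call = classify_pattern(tree, taxonomy, cfg, candidate_id=spec.id)
            verdict = None
            if (
                call.topology_pattern == TopologyPattern.D_NO_FUNGAL
                and spec.planted_contamination != "none"
            ):
                context = generate_contig(
                    spec.planted_contamination, seed=spec.seed,
                    focal_kingdom=cfg.focal_kingdom,
                )
                verdict = assess_contamination(
                    context, focal_kingdom=cfg.focal_kingdom
                ).verdict
            rows.append(
                finalize_call(call, verdict, indeterminate_is_clean=indeterminate_is_clean)
            )
        except Exception as exc:
            raise RuntimeError(f"candidate {spec.id}: {exc}") from exc
    return RunReport(name=manifest.name, master_seed=manifest.master_seed, rows=tuple(rows))


def species_tree_from_taxonomy(taxonomy: TaxonomyTable) -> SpeciesTree:
    """Rooted species tree mirroring the taxonomy hierarchy.

    Internal nodes are labeled with their taxon names so that an inferred
    transfer node reads as the narrowest taxon containing the receptors.
    """
    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    root.label = "root"
    index: dict[tuple[str, ...], dendropy.Node] = {(): root}
    for sid in sorted(taxonomy.ids()):
        lineage = taxonomy[sid]
        parent = root
        path: tuple[str, ...] = ()
        for _, name in lineage.pairs[:-1]:
            path = path + (name,)
            node = index.get(path)
            if node is None:
                node = dendropy.Node()
                node.label = name
                parent.add_child(node)
                index[path] = node
            parent = node
        leaf = dendropy.Node()
        leaf.taxon = tns.require_taxon(lineage.species or sid)
        parent.add_child(leaf)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    return SpeciesTree(tree)


def map_transfers(
    report: RunReport,
    species_tree: SpeciesTree,
    receptor_map: Mapping[str, Iterable[str]] | None = None,
) -> RunReport:
    """Attach a minimum-transfer-node table for every final HGT call.

    ``receptor_map`` maps candidate id → receptor species; when omitted, the
    focal-patch leaf ids of each call are used (in the synthetic pipeline
    those are species names).  Returns a new report; every HGT row appears
    exactly once in the table.
    """
    transfers = []
    for row in report.rows:
        if row.final_call != FinalCall.HGT:
            continue
        if receptor_map is not None:
            receptors = sorted(set(receptor_map[row.candidate_id]))
        else:
            receptors = sorted(set(row.focal_patch))
        node = infer_transfer_node(species_tree, receptors)
        transfers.append(
            {
                "candidate_id": row.candidate_id,
                "transfer_node": node_label(node),
                "n_receptors": len(receptors),
            }
        )
    return RunReport(
        name=report.name,
        master_seed=report.master_seed,
        rows=report.rows,
        transfers=tuple(transfers),
    )


def write_calls_tsv(path: str | Path, rows: Sequence[PatternCall]) -> None:
    header = (
        "candidate_id\ttopology_pattern\tfinal_call\tfocal_patch_size\t"
        "focal_patch_span\toutside_fungal_count\tdonor_count\t"
        "contamination_verdict\tfocal_patch\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.candidate_id,
                        r.topology_pattern.value,
                        r.final_call.value if r.final_call else "",
                        str(len(r.focal_patch)),
                        r.focal_patch_span or "",
                        str(r.outside_fungal_count),
                        str(r.donor_count),
                        r.contamination.value if r.contamination else "",
                        ";".join(r.focal_patch),
                    ]
                )
                + "\n"
            )


def read_calls_tsv(path: str | Path) -> list[PatternCall]:
    rows: list[PatternCall] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("candidate_id\t"):
            raise ValueError(f"{path}: missing calls header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: expected 9 columns, got {len(parts)}")
            (cid, tp, fc, _size, span, outside, donors, verdict, patch) = parts
            rows.append(
                PatternCall(
                    candidate_id=cid,
                    topology_pattern=TopologyPattern(tp),
                    final_call=FinalCall(fc) if fc else None,
                    focal_patch=tuple(patch.split(";")) if patch else (),
                    focal_patch_span=span or None,
                    outside_fungal_count=int(outside),
                    donor_count=int(donors),
                    contamination=Verdict(verdict) if verdict else None,
                )
            )
    return rows
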