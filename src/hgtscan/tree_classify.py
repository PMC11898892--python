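"""Unrooted gene-tree topology classification for HGT candidate triage.

The central question for each candidate gene tree is *where the fungal leaves
sit relative to everything else*.  On an unrooted tree the right notion of
monophyly is the **clan**: a leaf set forming one side of some edge
bipartition.  Fungal leaves partition into **patches** — maximal all-fungal
clans — and the patch containing the focal (candidate) leaf, together with
its taxonomic span and the remaining fungal leaves, decides the pattern:

- ``A_HGT`` — the focal patch is taxonomically narrow (confined to a single
  class by default), no fungal leaves lie outside it, and enough donor
  (non-fungal) leaves surround it: the nesting expected of a genuine
  interkingdom transfer.
- ``B_VERTICAL`` — the fungal leaves form a wide (multi-class) cohesive
  group, or additional fungal homologs sit outside the focal patch: ordinary
  vertical descent.
- ``C_ANCIENT`` — a *sparse* focal patch spanning multiple fungal phyla:
  explaining it as HGT would require a transfer near the origin of fungi
  followed by loss in most descendants, so it is set aside as
  ancient-transfer-or-loss.
- ``D_NO_FUNGAL`` — the focal leaf is the only fungal leaf; either a genuine
  species-specific acquisition or assembly contamination, resolved by the
  contig triage (:mod:`hgtscan.contamination`).
- ``UNINFORMATIVE`` — too few leaves (or too few donors) to support any of
  the above.

:func:`finalize_call` folds the contamination verdict into the topology
pattern to produce the final call; :func:`infer_transfer_node` maps accepted
HGT cases to their minimum transfer node (the MRCA of the receptor species)
on a rooted species tree.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from hgtscan.contamination import Verdict
from hgtscan.taxonomy import (
    Lineage,
    TaxonomyTable,
    is_member,
    rank_at_or_rootward,
    rank_index,
    span_rank,
)

__all__ = [
    "TopologyPattern",
    "FinalCall",
    "GeneTree",
    "SpeciesTree",
    "ClassifyConfig",
    "PatternCall",
    "parse_newick",
    "is_clan",
    "fungal_patches",
    "classify_pattern",
    "finalize_call",
    "infer_transfer_node",
]


class TopologyPattern(str, enum.Enum):
    A_HGT = "A_HGT"
    B_VERTICAL = "B_VERTICAL"
    C_ANCIENT = "C_ANCIENT"
    D_NO_FUNGAL = "D_NO_FUNGAL"
    UNINFORMATIVE = "UNINFORMATIVE"


class FinalCall(str, enum.Enum):
    HGT = "HGT"
    VERTICAL = "VERTICAL"
    ANCIENT_TRANSFER_OR_LOSS = "ANCIENT_TRANSFER_OR_LOSS"
    CONTAMINATION = "CONTAMINATION"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class ClassifyConfig:
    """Knobs of the topology classifier.

    ``hgt_max_span_rank`` is the widest taxonomic span a focal patch may have
    and still look like a recent transfer (default: confined to one class).
    ``ancient_span_rank`` is the span at or beyond which a *sparse* patch is
    read as ancient-transfer-plus-loss (default: multiple phyla).
    ``sparse_max_patch`` separates sparse patches (candidate C) from dense
    fungal groups (B).  ``support_collapse``, when set, polytomizes internal
    edges whose support falls below the threshold before classification.
    """

    focal_kingdom: str = "Fungi"
    focal_subtaxon: str = "Pezizomycotina"
    hgt_max_span_rank: str = "class"
    ancient_span_rank: str = "phylum"
    sparse_max_patch: int = 10
    min_informative_leaves: int = 4
    min_donor_leaves: int = 3
    support_collapse: float | None = None

    def __post_init__(self) -> None:
        if rank_index(self.hgt_max_span_rank) >= rank_index("species"):
            raise ValueError("hgt_max_span_rank must be rootward of species")
        if rank_index(self.ancient_span_rank) >= rank_index(self.hgt_max_span_rank):
            raise ValueError("ancient_span_rank must be rootward of hgt_max_span_rank")
        if self.sparse_max_patch < 1 or self.min_informative_leaves < 1 or self.min_donor_leaves < 1:
            raise ValueError("count thresholds must be positive")
        if self.support_collapse is not None and not 0.0 <= self.support_collapse <= 1.0:
            raise ValueError("support_collapse must lie in [0,1]")


@dataclass(frozen=True)
class PatternCall:
    """Classification outcome for one candidate tree."""

    candidate_id: str
    topology_pattern: TopologyPattern
    final_call: FinalCall | None = None
    focal_patch: tuple[str, ...] = ()
    focal_patch_span: str | None = None
    outside_fungal_count: int = 0
    donor_count: int = 0
    contamination: Verdict | None = None


class GeneTree:
    """An unrooted, leaf-labeled gene tree with one focal candidate leaf.

    Internally held as a (arbitrarily) rooted dendropy tree; every operation
    is defined on the unrooted topology, so the stored rooting is never
    semantically meaningful.  Numeric internal-node labels are interpreted as
    edge support values in [0, 1].
    """

    def __init__(self, tree: dendropy.Tree, focal_id: str) -> None:
        self._tree = tree
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaves) != len(set(leaves)):
            raise ValueError("gene tree has duplicate leaf labels")
        if len(leaves) < 3:
            raise ValueError(f"gene tree needs >= 3 leaves, got {len(leaves)}")
        if focal_id not in leaves:
            raise ValueError(f"focal id {focal_id!r} is not a leaf of the tree")
        for node in tree.preorder_internal_node_iter():
            s = _numeric_label(node)
            if s is not None and not 0.0 <= s <= 1.0:
                raise ValueError(f"support value out of [0,1]: {s}")
        self.focal_id = focal_id
        self._leaves = frozenset(leaves)
        self._sides: list[frozenset[str]] | None = None

    @property
    def leaf_ids(self) -> frozenset[str]:
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def edge_sides(self) -> list[frozenset[str]]:
        """One leaf set per edge: the side not containing the stored root."""
        if self._sides is None:
            sides = []
            for node in self._tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                sides.append(
                    frozenset(lf.taxon.label for lf in node.leaf_iter())
                )
            self._sides = sides
        return self._sides

    def supports(self) -> dict[frozenset[str], float]:
        """Map edge side (leaf set below the edge) → numeric support, where present."""
        out = {}
        for node in self._tree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            s = _numeric_label(node)
            if s is not None:
                out[frozenset(lf.taxon.label for lf in node.leaf_iter())] = s
        return out

    def collapse_low_support(self, threshold: float) -> "GeneTree":
        """New tree with internal edges of support < *threshold* collapsed."""
        clone = self._tree.clone(depth=1)
        doomed = []
        for node in clone.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            s = _numeric_label(node)
            if s is not None and s < threshold:
                doomed.append(node)
        for node in doomed:
            node.edge.collapse()
        return GeneTree(clone, self.focal_id)

    def write_newick(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.as_newick())

    def as_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
            + "\n"
        )


def _numeric_label(node: dendropy.Node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def parse_newick(source: str | Path, focal_id: str) -> GeneTree:
    """Parse a Newick gene tree (path or string) with its focal leaf id.

    Internal node labels are read verbatim; numeric ones act as support
    values.  Polytomies are preserved.
    """
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source
    ):
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick: {exc}") from None
    return GeneTree(tree, focal_id)


def is_clan(tree: GeneTree, leafset: Iterable[str]) -> bool:
    """True iff *leafset* is one side of some edge bipartition of the tree."""
    s = frozenset(leafset)
    if not s:
        raise ValueError("empty leaf set has no clan status")
    if s == tree.leaf_ids:
        raise ValueError("leaf set equal to all leaves has no clan status")
    if not s <= tree.leaf_ids:
        missing = sorted(s - tree.leaf_ids)
        raise ValueError(f"leaf ids not in tree: {missing}")
    allleaves = tree.leaf_ids
    for side in tree.edge_sides():
        if side == s or allleaves - side == s:
            return True
    return False


def fungal_patches(
    tree: GeneTree, taxonomy: TaxonomyTable, config: ClassifyConfig | None = None
) -> list[frozenset[str]]:
    """Maximal all-focal-kingdom clans; a partition of the fungal leaves.

    Every fungal leaf is a (singleton) clan via its own pendant edge, so the
    patches always cover the fungal leaves; maximality plus the presence of a
    non-fungal leaf guarantees pairwise disjointness.
    """
    cfg = config or ClassifyConfig()
    fungal = frozenset(
        leaf for leaf in tree.leaf_ids if is_member(taxonomy[leaf], cfg.focal_kingdom)
    )
    if not fungal:
        return []
    if fungal == tree.leaf_ids:
        return [fungal]
    allleaves = tree.leaf_ids
    candidates: set[frozenset[str]] = set()
    for side in tree.edge_sides():
        for s in (side, allleaves - side):
            if s and s <= fungal:
                candidates.add(s)
    maximal: list[frozenset[str]] = []
    for s in sorted(candidates, key=len, reverse=True):
        if not any(s < kept for kept in maximal):
            maximal.append(s)
    return sorted(maximal, key=lambda s: min(s))


def classify_pattern(
    tree: GeneTree,
    taxonomy: TaxonomyTable,
    config: ClassifyConfig | None = None,
    candidate_id: str | None = None,
) -> PatternCall:
    """Assign one of the five topology patterns to a candidate tree.

    Decision sequence (see module docstring for the rationale):

    1. fewer than ``min_informative_leaves`` leaves → UNINFORMATIVE;
    2. focal leaf is the only focal-kingdom leaf → D_NO_FUNGAL;
    3. otherwise let P be the fungal patch containing the focal leaf and S
       its taxonomic span;
    4. S at or rootward of ``hgt_max_span_rank`` (patch spans several classes
       or phyla): sparse multi-phylum patches → C_ANCIENT, anything dense →
       B_VERTICAL;
    5. S tipward of ``hgt_max_span_rank`` (single class): A_HGT when no
       fungal leaves lie outside P and at least ``min_donor_leaves`` donors
       are present; too few donors → UNINFORMATIVE; fungal leaves outside P
       → B_VERTICAL.
    """
    cfg = config or ClassifyConfig()
    cid = candidate_id if candidate_id is not None else tree.focal_id
    focal_lineage = taxonomy[tree.focal_id]
    if not is_member(focal_lineage, cfg.focal_kingdom):
        raise ValueError(
            f"focal leaf {tree.focal_id!r} is not in the focal kingdom "
            f"{cfg.focal_kingdom!r}"
        )
    if cfg.support_collapse is not None:
        tree = tree.collapse_low_support(cfg.support_collapse)

    fungal = frozenset(
        leaf for leaf in tree.leaf_ids if is_member(taxonomy[leaf], cfg.focal_kingdom)
    )
    donor_count = tree.n_leaves - len(fungal)

    if tree.n_leaves < cfg.min_informative_leaves:
        return PatternCall(
            candidate_id=cid,
            topology_pattern=TopologyPattern.UNINFORMATIVE,
            donor_count=donor_count,
        )
    if fungal == {tree.focal_id}:
        return PatternCall(
            candidate_id=cid,
            topology_pattern=TopologyPattern.D_NO_FUNGAL,
            focal_patch=(tree.focal_id,),
            focal_patch_span="uniform",
            donor_count=donor_count,
        )

    patches = fungal_patches(tree, taxonomy, cfg)
    patch = next(p for p in patches if tree.focal_id in p)
    span = span_rank([taxonomy[leaf] for leaf in patch])
    outside = len(fungal) - len(patch)
    evidence = dict(
        candidate_id=cid,
        focal_patch=tuple(sorted(patch)),
        focal_patch_span=span,
        outside_fungal_count=outside,
        donor_count=donor_count,
    )

    if span != "uniform" and rank_at_or_rootward(span, cfg.hgt_max_span_rank):
        # patch spans multiple classes (or wider)
        if len(patch) <= cfg.sparse_max_patch and rank_at_or_rootward(
            span, cfg.ancient_span_rank
        ):
            return PatternCall(topology_pattern=TopologyPattern.C_ANCIENT, **evidence)
        return PatternCall(topology_pattern=TopologyPattern.B_VERTICAL, **evidence)

    # patch confined to a single class
    if outside == 0 and donor_count >= cfg.min_donor_leaves:
        return PatternCall(topology_pattern=TopologyPattern.A_HGT, **evidence)
    if donor_count < cfg.min_donor_leaves:
        return PatternCall(topology_pattern=TopologyPattern.UNINFORMATIVE, **evidence)
    return PatternCall(topology_pattern=TopologyPattern.B_VERTICAL, **evidence)


def finalize_call(
    pattern: PatternCall,
    verdict: Verdict | None = None,
    indeterminate_is_clean: bool = False,
) -> PatternCall:
    """Fold the contamination verdict into a topology pattern.

    - A_HGT → HGT (a contaminated/indeterminate contig, if one was checked,
      demotes it to CONTAMINATION);
    - D_NO_FUNGAL requires a verdict: clean → HGT, otherwise CONTAMINATION
      (indeterminate counts as not-clean unless ``indeterminate_is_clean``);
    - B → VERTICAL; C → ANCIENT_TRANSFER_OR_LOSS; UNINFORMATIVE stays.
    """
    tp = pattern.topology_pattern

    def _clean(v: Verdict) -> bool:
        return v == Verdict.CLEAN or (
            v == Verdict.INDETERMINATE and indeterminate_is_clean
        )

    if tp == TopologyPattern.A_HGT:
        if verdict is None or _clean(verdict):
            final = FinalCall.HGT
        else:
            final = FinalCall.CONTAMINATION
    elif tp == TopologyPattern.D_NO_FUNGAL:
        if verdict is None:
            raise ValueError(
                f"candidate {pattern.candidate_id!r}: pattern D requires a "
                "contamination verdict"
            )
        final = FinalCall.HGT if _clean(verdict) else FinalCall.CONTAMINATION
    elif tp == TopologyPattern.B_VERTICAL:
        final = FinalCall.VERTICAL
    elif tp == TopologyPattern.C_ANCIENT:
        final = FinalCall.ANCIENT_TRANSFER_OR_LOSS
    else:
        final = FinalCall.UNINFORMATIVE
    return PatternCall(
        candidate_id=pattern.candidate_id,
        topology_pattern=tp,
        final_call=final,
        focal_patch=pattern.focal_patch,
        focal_patch_span=pattern.focal_patch_span,
        outside_fungal_count=pattern.outside_fungal_count,
        donor_count=pattern.donor_count,
        contamination=verdict,
    )


class SpeciesTree:
    """A rooted species tree with unique species-name leaves."""

    def __init__(self, tree: dendropy.Tree) -> None:
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(leaves) != len(set(leaves)):
            raise ValueError("species tree has duplicate leaf names")
        self._tree = tree
        self._leaves = frozenset(leaves)
        self._tree.is_rooted = True
        self._tree.encode_bipartitions()

    @classmethod
    def from_newick(cls, source: str | Path) -> "SpeciesTree":
        if isinstance(source, Path) or ("(" not in str(source)):
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = str(source)
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls(tree)

    @property
    def leaf_names(self) -> frozenset[str]:
        return self._leaves

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def as_newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
            + "\n"
        )


def infer_transfer_node(
    species_tree: SpeciesTree, receptor_species: Iterable[str]
) -> dendropy.Node:
    """Most recent common ancestor of the receptor species (minimum transfer node).

    A single receptor species maps to its own leaf — the latest point on the
    species tree at which the transfer could have happened.
    """
    species = sorted(set(receptor_species))
    if not species:
        raise ValueError("receptor species set is empty")
    for sp in species:
        if sp not in species_tree.leaf_names:
            raise ValueError(f"receptor species not in species tree: {sp!r}")
    tree = species_tree.dendropy_tree
    if len(species) == 1:
        return tree.find_node_with_taxon_label(species[0])
    return tree.mrca(taxon_labels=species)


def node_label(node: dendropy.Node) -> str:
    """Readable label for a species-tree node (leaf taxon or internal label)."""
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
    return f"mrca({leaves[0]},{leaves[-1]})"
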