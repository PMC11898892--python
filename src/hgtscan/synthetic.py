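"""Seeded generators for taxonomies, gene trees, hit tables and contigs.

Every fixture carries planted ground truth and is re-checked against it
before being handed out: a gene tree generated for pattern A is classified
with the default classifier and generation *fails* if the planted pattern is
not recovered.  This self-verification makes the generators a executable
contract between the simulator and the classifier.

The replication manifests encode the composition of the two candidate sets
the pipeline is meant to reproduce end-to-end:

- ``denovo`` — 246 candidates from the proteome-wide screen: 1 no-fungal
  case on a clean contig (the single accepted de novo HGT), 134 vertical
  topologies, 10 sparse multi-phylum (ancient) topologies and 101 no-fungal
  cases on contaminated contigs.
- ``literature`` — 275 previously reported candidates: 7 HGT-compatible
  nestings, 243 vertical, 21 ancient, 2 contaminated and 2 uninformative.
- ``combined`` — their concatenation (521 candidates).

Per-scenario seeds are derived from the manifest's master seed by stable
hashing of the scenario id, so any scenario can be regenerated in isolation.
"""

from __future__ import annotations

import json
import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy

from hgtscan.contamination import ContigContext, Verdict, assess_contamination
from hgtscan.screening import HomologHit, ScreenConfig, compute_lpi, eligible_hits, screen_candidates
from hgtscan.taxonomy import Lineage, TaxonomyTable, is_member
from hgtscan.tree_classify import (
    ClassifyConfig,
    GeneTree,
    TopologyPattern,
    classify_pattern,
)

__all__ = [
    "GenerationError",
    "ScenarioSpec",
    "ReplicationManifest",
    "TaxonomyShape",
    "generate_taxonomy",
    "generate_tree",
    "generate_hits",
    "generate_contig",
    "build_manifest",
]


class GenerationError(RuntimeError):
    """A generated fixture failed self-verification against its planted label."""


# ---------------------------------------------------------------------------
# taxonomy


@dataclass(frozen=True)
class TaxonomyShape:
    """Breadth of the toy taxonomy below each class."""

    n_orders: int = 2
    n_families: int = 2
    n_genera: int = 2
    n_species: int = 2

    def __post_init__(self) -> None:
        for v in (self.n_orders, self.n_families, self.n_genera, self.n_species):
            if v < 1:
                raise ValueError("taxonomy shape parameters must be positive")


# (superkingdom, kingdom-or-None, phylum, classes)
_TOY_CLADES: tuple[tuple[str, str | None, str, tuple[str, ...]], ...] = (
    (
        "Eukaryota",
        "Fungi",
        "Ascomycota",
        (
            "Pezizomycotina",
            "Sordariomycetes",
            "Dothideomycetes",
            "Eurotiomycetes",
            "Leotiomycetes",
        ),
    ),
    ("Eukaryota", "Fungi", "Basidiomycota", ("Agaricomycetes",)),
    ("Eukaryota", "Fungi", "Chytridiomycota", ("Chytridiomycetes",)),
    ("Eukaryota", "Fungi", "Mucoromycota", ("Mucoromycetes",)),
    ("Eukaryota", "Viridiplantae", "Streptophyta", ("Magnoliopsida",)),
    ("Bacteria", None, "Proteobacteria", ("Gammaproteobacteria", "Alphaproteobacteria")),
    ("Bacteria", None, "Bacillota", ("Bacilli",)),
    ("Bacteria", None, "Actinomycetota", ("Actinomycetes",)),
)


def generate_taxonomy(seed: int = 0, shape: TaxonomyShape | None = None) -> TaxonomyTable:
    """Emit the toy species taxonomy (one entry per species, id = species name).

    The hierarchy is fixed: two superkingdoms, a Fungi kingdom holding an
    Ascomycota phylum with a Pezizomycotina-like focal class plus three other
    fungal phyla, a plant kingdom and three bacterial phyla (bacterial
    lineages skip the kingdom rank, as reference lineages do).  Names below
    class level are synthetic and fully determined by *shape*; the same seed
    always yields the identical table.
    """
    del seed  # breadth and names are deterministic; the seed is part of the contract
    shape = shape or TaxonomyShape()
    table = TaxonomyTable()
    for superkingdom, kingdom, phylum, classes in _TOY_CLADES:
        for cls in classes:
            for o in range(1, shape.n_orders + 1):
                order = f"{cls}_o{o}"
                for f in range(1, shape.n_families + 1):
                    family = f"{order}f{f}"
                    for g in range(1, shape.n_genera + 1):
                        genus = f"{family}g{g}"
                        for s in range(1, shape.n_species + 1):
                            species = f"{genus}_sp{s}"
                            pairs = [("superkingdom", superkingdom)]
                            if kingdom is not None:
                                pairs.append(("kingdom", kingdom))
                            pairs += [
                                ("phylum", phylum),
                                ("class", cls),
                                ("order", order),
                                ("family", family),
                                ("genus", genus),
                                ("species", species),
                            ]
                            table.add(species, Lineage.from_pairs(pairs))
    return table


def _species_of(
    taxonomy: TaxonomyTable,
    *,
    superkingdom: str | None = None,
    kingdom: str | None = None,
    phylum: str | None = None,
    class_: str | None = None,
) -> list[str]:
    out = []
    for sid, lin in taxonomy.items():
        if superkingdom and lin.name_at("superkingdom") != superkingdom:
            continue
        if kingdom and lin.name_at("kingdom") != kingdom:
            continue
        if phylum and lin.name_at("phylum") != phylum:
            continue
        if class_ and lin.name_at("class") != class_:
            continue
        out.append(sid)
    return sorted(out)


# ---------------------------------------------------------------------------
# scenarios and manifests


@dataclass(frozen=True)
class ScenarioSpec:
    """One planted gene-tree scenario."""

    id: str
    planted_pattern: TopologyPattern
    planted_contamination: str  # "clean" | "contaminated" | "none"
    params: dict
    seed: int

    def __post_init__(self) -> None:
        if self.planted_contamination not in ("clean", "contaminated", "none"):
            raise ValueError(
                f"bad planted_contamination: {self.planted_contamination!r}"
            )
        if self.planted_pattern == TopologyPattern.D_NO_FUNGAL:
            if self.planted_contamination == "none":
                raise ValueError("pattern D scenarios need a contig verdict")
        elif self.planted_contamination != "none":
            raise ValueError("only pattern D scenarios carry a contig verdict")


@dataclass(frozen=True)
class ReplicationManifest:
    name: str
    master_seed: int
    specs: tuple[ScenarioSpec, ...]

    _EXPECTED_SIZES = {"denovo": 246, "literature": 275, "combined": 521}

    def __post_init__(self) -> None:
        expected = self._EXPECTED_SIZES.get(self.name)
        if expected is not None and len(self.specs) != expected:
            raise ValueError(
                f"manifest {self.name!r} must have {expected} scenarios, "
                f"got {len(self.specs)}"
            )

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "master_seed": self.master_seed,
            "specs": [
                {
                    "id": s.id,
                    "planted_pattern": s.planted_pattern.value,
                    "planted_contamination": s.planted_contamination,
                    "params": s.params,
                    "seed": s.seed,
                }
                for s in self.specs
            ],
        }

    @classmethod
    def from_json(cls, payload: dict) -> "ReplicationManifest":
        return cls(
            name=payload["name"],
            master_seed=payload["master_seed"],
            specs=tuple(
                ScenarioSpec(
                    id=s["id"],
                    planted_pattern=TopologyPattern(s["planted_pattern"]),
                    planted_contamination=s["planted_contamination"],
                    params=dict(s["params"]),
                    seed=s["seed"],
                )
                for s in payload["specs"]
            ),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "ReplicationManifest":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


def _spec_seed(spec_id: str, master_seed: int) -> int:
    """Stable per-scenario seed below 2**31."""
    return zlib.crc32(f"{spec_id}:{master_seed}".encode()) & 0x7FFFFFFF


def _draw_params(pattern: TopologyPattern, rng: random.Random) -> dict:
    if pattern == TopologyPattern.A_HGT:
        return {
            "n_focal_patch": rng.randint(2, 8),
            "n_outside_fungal": 0,
            "n_donor": rng.randint(8, 20),
        }
    if pattern == TopologyPattern.B_VERTICAL:
        return {
            "n_focal_patch": rng.randint(20, 40),
            "n_classes": rng.randint(3, 5),
            "n_outside_fungal": 0,
            "n_donor": rng.randint(8, 20),
        }
    if pattern == TopologyPattern.C_ANCIENT:
        return {
            "n_focal_patch": rng.randint(2, 6),
            "n_outside_fungal": 0,
            "n_donor": rng.randint(8, 20),
        }
    if pattern == TopologyPattern.D_NO_FUNGAL:
        return {"n_focal_patch": 1, "n_outside_fungal": 0, "n_donor": rng.randint(8, 20)}
    return {"n_leaves": 3}  # UNINFORMATIVE


_COMPOSITIONS = {
    "denovo": (
        (TopologyPattern.D_NO_FUNGAL, "clean", 1),
        (TopologyPattern.B_VERTICAL, "none", 134),
        (TopologyPattern.C_ANCIENT, "none", 10),
        (TopologyPattern.D_NO_FUNGAL, "contaminated", 101),
    ),
    "literature": (
        (TopologyPattern.A_HGT, "none", 7),
        (TopologyPattern.B_VERTICAL, "none", 243),
        (TopologyPattern.C_ANCIENT, "none", 21),
        (TopologyPattern.D_NO_FUNGAL, "contaminated", 2),
        (TopologyPattern.UNINFORMATIVE, "none", 2),
    ),
}


def build_manifest(name: str, master_seed: int) -> ReplicationManifest:
    """Build a replication manifest (``denovo``, ``literature`` or ``combined``)."""
    if name == "combined":
        denovo = build_manifest("denovo", master_seed)
        literature = build_manifest("literature", master_seed)
        return ReplicationManifest(
            name="combined",
            master_seed=master_seed,
            specs=denovo.specs + literature.specs,
        )
    try:
        composition = _COMPOSITIONS[name]
    except KeyError:
        raise ValueError(f"unknown manifest name: {name!r}") from None
    specs: list[ScenarioSpec] = []
    idx = 0
    for pattern, contamination, count in composition:
        for _ in range(count):
            idx += 1
            spec_id = f"{name}-{idx:04d}"
            seed = _spec_seed(spec_id, master_seed)
            rng = random.Random(seed)
            specs.append(
                ScenarioSpec(
                    id=spec_id,
                    planted_pattern=pattern,
                    planted_contamination=contamination,
                    params=_draw_params(pattern, rng),
                    seed=seed,
                )
            )
    return ReplicationManifest(name=name, master_seed=master_seed, specs=tuple(specs))


# ---------------------------------------------------------------------------
# gene trees


def _make_leaf(tns: dendropy.TaxonNamespace, name: str) -> dendropy.Node:
    node = dendropy.Node()
    node.taxon = tns.require_taxon(name)
    return node


def _random_join(rng: random.Random, subtrees: list[dendropy.Node]) -> dendropy.Node:
    """Coalescent-style random sequential joining into one rooted subtree."""
    pool = list(subtrees)
    while len(pool) > 1:
        i = rng.randrange(len(pool))
        a = pool.pop(i)
        j = rng.randrange(len(pool))
        b = pool.pop(j)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        pool.append(parent)
    return pool[0]


def _graft_into(
    rng: random.Random, host_root: dendropy.Node, graft: dendropy.Node
) -> None:
    """Bisect a random edge of the host subtree and hang *graft* there."""
    edges = [n for n in host_root.preorder_iter() if n.parent_node is not None]
    if not edges:
        raise GenerationError("host subtree too small to graft into")
    child = rng.choice(edges)
    parent = child.parent_node
    parent.remove_child(child)
    hub = dendropy.Node()
    hub.add_child(child)
    hub.add_child(graft)
    parent.add_child(hub)


def _finish_tree(
    rng: random.Random, tns: dendropy.TaxonNamespace, root: dendropy.Node, focal: str
) -> GeneTree:
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = rng.expovariate(1.0)
        if node.parent_node is not None and not node.is_leaf():
            node.label = f"{rng.uniform(0.8, 1.0):.3f}"
    return GeneTree(tree, focal)


def _sample_b_fungal(
    rng: random.Random, taxonomy: TaxonomyTable, n_fungal: int, n_classes: int
) -> list[str]:
    """Fungal leaves for a dense vertical clan spanning >= 3 Ascomycota classes."""
    classes = ["Pezizomycotina"] + rng.sample(
        ["Sordariomycetes", "Dothideomycetes", "Eurotiomycetes", "Leotiomycetes"],
        n_classes - 1,
    )
    pools = {c: _species_of(taxonomy, class_=c) for c in classes}
    chosen: list[str] = []
    # one from each class first so the span is guaranteed, then fill round-robin
    for c in classes:
        chosen.append(pools[c].pop(rng.randrange(len(pools[c]))))
    turn = 0
    while len(chosen) < n_fungal:
        c = classes[turn % len(classes)]
        if pools[c]:
            chosen.append(pools[c].pop(rng.randrange(len(pools[c]))))
        turn += 1
        if all(not p for p in pools.values()):
            break
    return chosen


def generate_tree(spec: ScenarioSpec, taxonomy: TaxonomyTable) -> GeneTree:
    """Generate the gene tree for one scenario and verify the planted pattern.

    Topologies are built by uniform random sequential joins within leaf
    compartments; the fungal compartment is then attached according to the
    planted pattern (grafted inside the donor subtree for A/C/D, sister to it
    for B).  Branch lengths are exponential(1); supports uniform(0.8, 1).
    Raises :class:`GenerationError` if the default classifier does not
    recover the planted pattern — a size/pattern contradiction in the
    scenario parameters surfaces at generation time, not at classification
    time.
    """
    rng = random.Random(spec.seed)
    tns = dendropy.TaxonNamespace()
    pattern = spec.planted_pattern
    p = spec.params

    pez = _species_of(taxonomy, class_="Pezizomycotina")
    donors_pool = _species_of(taxonomy, superkingdom="Bacteria")

    if pattern == TopologyPattern.UNINFORMATIVE:
        n_leaves = int(p.get("n_leaves", 3))
        focal = rng.choice(pez)
        donor_leaves = rng.sample(donors_pool, n_leaves - 1)
        root = _random_join(rng, [_make_leaf(tns, x) for x in [focal] + donor_leaves])
        gene_tree = _finish_tree(rng, tns, root, focal)
    else:
        n_donor = int(p["n_donor"])
        donor_leaves = rng.sample(donors_pool, n_donor)
        donor_root = _random_join(rng, [_make_leaf(tns, x) for x in donor_leaves])

        if pattern == TopologyPattern.A_HGT:
            patch = rng.sample(pez, int(p["n_focal_patch"]))
            focal = patch[0]
            patch_root = _random_join(rng, [_make_leaf(tns, x) for x in patch])
            _graft_into(rng, donor_root, patch_root)
            root = donor_root
        elif pattern == TopologyPattern.B_VERTICAL:
            fungal = _sample_b_fungal(
                rng, taxonomy, int(p["n_focal_patch"]), int(p.get("n_classes", 3))
            )
            focal = next(
                x for x in fungal if taxonomy[x].name_at("class") == "Pezizomycotina"
            )
            fungal_root = _random_join(rng, [_make_leaf(tns, x) for x in fungal])
            root = dendropy.Node()
            root.add_child(fungal_root)
            root.add_child(donor_root)
        elif pattern == TopologyPattern.C_ANCIENT:
            n_patch = int(p["n_focal_patch"])
            other_phyla = _species_of(taxonomy, kingdom="Fungi")
            other_phyla = [
                x for x in other_phyla if taxonomy[x].name_at("phylum") != "Ascomycota"
            ]
            focal = rng.choice(pez)
            n_other = max(1, n_patch - 1 - rng.randint(0, max(0, n_patch - 2)))
            others = rng.sample(other_phyla, n_other)
            extra_pez = rng.sample(
                [x for x in pez if x != focal], n_patch - 1 - n_other
            )
            patch = [focal] + extra_pez + others
            patch_root = _random_join(rng, [_make_leaf(tns, x) for x in patch])
            _graft_into(rng, donor_root, patch_root)
            root = donor_root
        elif pattern == TopologyPattern.D_NO_FUNGAL:
            focal = rng.choice(pez)
            _graft_into(rng, donor_root, _make_leaf(tns, focal))
            root = donor_root
        else:  # pragma: no cover - exhaustive over the enum
            raise ValueError(f"unknown pattern {pattern!r}")
        gene_tree = _finish_tree(rng, tns, root, focal)

    recovered = classify_pattern(
        gene_tree, taxonomy, ClassifyConfig(), candidate_id=spec.id
    ).topology_pattern
    if recovered != pattern:
        raise GenerationError(
            f"scenario {spec.id}: planted {pattern.value} but classifier "
            f"recovered {recovered.value}"
        )
    return gene_tree


# ---------------------------------------------------------------------------
# hit tables


def generate_hits(
    planted_lpi_class: str,
    seed: int,
    taxonomy: TaxonomyTable,
    config: ScreenConfig | None = None,
) -> tuple[str, Lineage, list[HomologHit]]:
    """Generate one screening fixture: (query id, query lineage, hits).

    ``"low"`` plants a hit set whose bitscore-weighted lineage overlap falls
    below the screening threshold with a non-fungal top hit (a candidate);
    ``"high"`` plants taxonomically close fungal hits (not a candidate).
    The fixture is verified against the screen before being returned.
    """
    if planted_lpi_class not in ("low", "high"):
        raise ValueError(f"planted_lpi_class must be 'low' or 'high': {planted_lpi_class!r}")
    cfg = config or ScreenConfig()
    rng = random.Random(seed)
    pez = _species_of(taxonomy, class_="Pezizomycotina")
    query_species = rng.choice(pez)
    query_lineage = taxonomy[query_species]
    query_id = query_species

    hits: list[HomologHit] = []

    def _hit(subject_species: str, bitscore: float) -> HomologHit:
        return HomologHit(
            query_id=query_id,
            subject_id=f"{subject_species}|h{len(hits)}",
            percent_identity=round(rng.uniform(40.0, 85.0), 1),
            query_coverage=round(rng.uniform(75.0, 98.0), 1),
            evalue=10 ** -rng.uniform(20, 80),
            bitscore=round(bitscore, 1),
            subject_lineage=taxonomy[subject_species],
        )

    if planted_lpi_class == "low":
        donors = rng.sample(_species_of(taxonomy, superkingdom="Bacteria"), rng.randint(6, 12))
        top = rng.uniform(300, 500)
        for i, sp in enumerate(donors):
            hits.append(_hit(sp, top - 10 * i))
        for sp in rng.sample([x for x in pez if x != query_species], rng.randint(0, 2)):
            hits.append(_hit(sp, rng.uniform(60, 80)))
    else:
        genus = query_lineage.name_at("genus")
        family = query_lineage.name_at("family")
        near = [
            x
            for x in pez
            if x != query_species
            and (
                taxonomy[x].name_at("genus") == genus
                or taxonomy[x].name_at("family") == family
            )
        ]
        others = [
            x
            for x in _species_of(taxonomy, kingdom="Fungi")
            if x != query_species and x not in near
        ]
        top = rng.uniform(300, 500)
        chosen = near + rng.sample(others, rng.randint(0, 2))
        for i, sp in enumerate(chosen):
            hits.append(_hit(sp, top - 15 * i))

    rng.shuffle(hits)

    result = screen_candidates({query_id: (query_lineage, hits)}, cfg)[0]
    want_flag = planted_lpi_class == "low"
    if result.is_candidate != want_flag:
        raise GenerationError(
            f"hit fixture (seed {seed}) planted {planted_lpi_class!r} but the "
            f"screen returned lpi={result.lpi:.3f}, candidate={result.is_candidate}"
        )
    return query_id, query_lineage, hits


# ---------------------------------------------------------------------------
# contigs


def generate_contig(verdict: str, seed: int, focal_kingdom: str = "Fungi") -> ContigContext:
    """Generate a contig context whose triage yields the requested verdict."""
    want = Verdict(verdict)
    rng = random.Random(seed)
    n_flank = rng.randint(3, 6)
    if want == Verdict.CONTAMINATED:
        kingdoms: list[str | None] = ["Bacteria"] * n_flank
        for i in range(n_flank):
            if rng.random() < 0.2:
                kingdoms[i] = None
        if all(k is None for k in kingdoms):
            kingdoms[rng.randrange(n_flank)] = "Bacteria"
    elif want == Verdict.CLEAN:
        kingdoms = [
            rng.choice(["Bacteria", focal_kingdom, None]) for _ in range(n_flank)
        ]
        if focal_kingdom not in kingdoms:
            kingdoms[rng.randrange(n_flank)] = focal_kingdom
    else:
        kingdoms = [None] * n_flank

    focal_index = rng.randrange(n_flank + 1)
    features: list[tuple[str, str | None]] = []
    ki = 0
    for i in range(n_flank + 1):
        if i == focal_index:
            features.append((f"c{seed}_focal", None))
        else:
            features.append((f"c{seed}_f{ki}", kingdoms[ki]))
            ki += 1
    context = ContigContext(
        contig_id=f"contig_{seed}", features=tuple(features), focal_index=focal_index
    )
    got = assess_contamination(context, focal_kingdom=focal_kingdom).verdict
    if got != want:
        raise GenerationError(
            f"contig fixture (seed {seed}) planted {want.value!r} but triage "
            f"returned {got.value!r}"
        )
    return context
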