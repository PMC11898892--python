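"""Clan analysis, topology pattern classification, and transfer mapping."""

import random

import dendropy
import networkx as nx
import pytest

from hgtscan.contamination import Verdict
from hgtscan.pipeline import species_tree_from_taxonomy
from hgtscan.synthetic import ScenarioSpec, generate_tree
from hgtscan.tree_classify import (
    ClassifyConfig,
    FinalCall,
    GeneTree,
    PatternCall,
    SpeciesTree,
    TopologyPattern,
    classify_pattern,
    finalize_call,
    fungal_patches,
    infer_transfer_node,
    is_clan,
    node_label,
    parse_newick,
)

CFG = ClassifyConfig()


def _ladder(names):
    """Caterpillar newick fragment over the given leaf names."""
    names = list(names)
    if len(names) == 1:
        return names[0]
    return f"({names[0]},{_ladder(names[1:])})"


def _pez(i):
    return f"Pezizomycotina_o{1 + (i // 8) % 2}f{1 + (i // 4) % 2}g{1 + (i // 2) % 2}_sp{1 + i % 2}"


def _bact(i):
    cls = ["Gammaproteobacteria", "Alphaproteobacteria", "Bacilli", "Actinomycetes"][i % 4]
    return f"{cls}_o{1 + (i // 4) % 2}f{1 + (i // 8) % 2}g1_sp{1 + (i // 16) % 2}"


# ---------------------------------------------------------------------------
# parsing


def test_parse_newick_basic_and_supports():
    tree = parse_newick("((A,B),(C,D));", focal_id="A")
    assert tree.n_leaves == 4 and tree.focal_id == "A"
    tree = parse_newick("((A,B)0.98,(C,D));", focal_id="A")
    assert 0.98 in tree.supports().values()
    assert tree.supports()[frozenset({"A", "B"})] == 0.98


def test_parse_newick_errors():
    with pytest.raises(ValueError, match="Z"):
        parse_newick("((A,B),(C,D));", focal_id="Z")
    with pytest.raises(ValueError, match="[Nn]ewick"):
        parse_newick("((A,B),(C,D);", focal_id="A")
    with pytest.raises(ValueError, match="3 leaves"):
        parse_newick("(A,B);", focal_id="A")


def test_support_out_of_range_rejected():
    with pytest.raises(ValueError, match="support"):
        parse_newick("((A,B)98,(C,D));", focal_id="A")


# ---------------------------------------------------------------------------
# clans


def test_is_clan_examples():
    tree = parse_newick("((A,B),(C,D));", focal_id="A")
    assert is_clan(tree, {"A", "B"})
    assert is_clan(tree, {"C", "D"})
    assert not is_clan(tree, {"A", "C"})
    assert is_clan(tree, {"A"})  # pendant edges make singleton clans
    assert is_clan(tree, {"B", "C", "D"})  # and their complements
    with pytest.raises(ValueError):
        is_clan(tree, set())
    with pytest.raises(ValueError):
        is_clan(tree, {"A", "B", "C", "D"})


def _random_gene_tree(rng, n_leaves, labels=None):
    from hgtscan.synthetic import _make_leaf, _random_join

    labels = labels or [f"L{i}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace()
    root = _random_join(rng, [_make_leaf(tns, x) for x in labels])
    t = dendropy.Tree(taxon_namespace=tns)
    t.seed_node = root
    return GeneTree(t, labels[0])


def _oracle_clans(tree):
    """All clans by graph bisection: remove each edge, read off components."""
    g = nx.Graph()
    leaf_label = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        g.add_node(id(node))
        if node.is_leaf():
            leaf_label[id(node)] = node.taxon.label
        for child in node.child_nodes():
            g.add_edge(id(node), id(child))
    clans = set()
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        for comp in nx.connected_components(g):
            side = frozenset(leaf_label[n] for n in comp if n in leaf_label)
            if side and side != frozenset(tree.leaf_ids):
                clans.add(side)
        g.add_edge(u, v)
    return clans


def test_is_clan_matches_graph_bisection_oracle_on_small_trees():
    rng = random.Random(42)
    for trial in range(15):
        n = rng.randint(4, 10)
        tree = _random_gene_tree(rng, n)
        oracle = _oracle_clans(tree)
        leaves = sorted(tree.leaf_ids)
        # check every nonempty proper subset
        for mask in range(1, 2 ** n - 1):
            subset = frozenset(leaves[i] for i in range(n) if mask >> i & 1)
            assert is_clan(tree, subset) == (subset in oracle)


def test_clan_complement_symmetry():
    rng = random.Random(7)
    tree = _random_gene_tree(rng, 9)
    leaves = sorted(tree.leaf_ids)
    for _ in range(200):
        k = rng.randint(1, len(leaves) - 1)
        s = frozenset(rng.sample(leaves, k))
        assert is_clan(tree, s) == is_clan(tree, tree.leaf_ids - s)


# ---------------------------------------------------------------------------
# fungal patches


def test_fungal_patches_single_clan(taxonomy):
    fungi = [_pez(i) for i in range(5)]
    bact = [_bact(i) for i in range(4)]
    nwk = f"({_ladder(fungi)},{_ladder(bact)});"
    tree = parse_newick(nwk, focal_id=fungi[0])
    patches = fungal_patches(tree, taxonomy, CFG)
    assert patches == [frozenset(fungi)]


def test_fungal_patches_two_singletons(taxonomy):
    f1, f2 = _pez(0), _pez(3)
    b = [_bact(i) for i in range(4)]
    nwk = f"((({f1},{b[0]}),{b[1]}),(({f2},{b[2]}),{b[3]}));"
    tree = parse_newick(nwk, focal_id=f1)
    patches = fungal_patches(tree, taxonomy, CFG)
    assert sorted(patches, key=min) == sorted(
        [frozenset({f1}), frozenset({f2})], key=min
    )


def test_fungal_patches_partition_and_match_oracle(taxonomy):
    rng = random.Random(5)
    fungal_pool = [_pez(i) for i in range(16)]
    bact_pool = [_bact(i) for i in range(16)]
    for _ in range(15):
        nf = rng.randint(1, 6)
        nb = rng.randint(1, 6)
        labels = rng.sample(fungal_pool, nf) + rng.sample(bact_pool, nb)
        rng.shuffle(labels)
        tree = _random_gene_tree(rng, len(labels), labels=labels)
        fungal = {x for x in labels if x in fungal_pool}
        patches = fungal_patches(tree, taxonomy, CFG)
        # partition of the fungal leaves
        assert set().union(*patches) == fungal
        assert sum(len(p) for p in patches) == len(fungal)
        # oracle: maximal elements of all all-fungal clans
        clans = [c for c in _oracle_clans(tree) if c <= fungal]
        maximal = {c for c in clans if not any(c < d for d in clans)}
        assert set(patches) == maximal


# ---------------------------------------------------------------------------
# pattern classification (the five archetypes)


def test_classify_pattern_a_hgt(taxonomy):
    fungi = [_pez(i) for i in range(6)]  # one class
    bact = [_bact(i) for i in range(8)]
    nwk = f"(({_ladder(bact[:4])},{_ladder(fungi)}),{_ladder(bact[4:])});"
    call = classify_pattern(parse_newick(nwk, focal_id=fungi[0]), taxonomy, CFG)
    assert call.topology_pattern == TopologyPattern.A_HGT
    assert call.focal_patch == tuple(sorted(fungi))
    assert call.outside_fungal_count == 0
    assert call.donor_count == 8


def test_classify_pattern_b_dense_multiclass(taxonomy):
    fungi = []
    for cls in ("Pezizomycotina", "Sordariomycetes", "Dothideomycetes", "Eurotiomycetes"):
        fungi += [f"{cls}_o{o}f{f}g1_sp{s}" for o in (1, 2) for f in (1, 2) for s in (1, 2)][:5]
    assert len(fungi) == 20
    bact = [_bact(i) for i in range(8)]
    nwk = f"({_ladder(fungi)},{_ladder(bact)});"
    focal = next(x for x in fungi if x.startswith("Pezizomycotina"))
    call = classify_pattern(parse_newick(nwk, focal_id=focal), taxonomy, CFG)
    assert call.topology_pattern == TopologyPattern.B_VERTICAL
    assert call.focal_patch_span == "class"


def test_classify_pattern_c_sparse_multiphylum(taxonomy):
    patch = [_pez(0), "Agaricomycetes_o1f1g1_sp1", "Chytridiomycetes_o1f1g1_sp1"]
    bact = [_bact(i) for i in range(8)]
    nwk = f"(({_ladder(bact[:4])},{_ladder(patch)}),{_ladder(bact[4:])});"
    call = classify_pattern(parse_newick(nwk, focal_id=patch[0]), taxonomy, CFG)
    assert call.topology_pattern == TopologyPattern.C_ANCIENT
    assert call.focal_patch_span == "phylum"


def test_classify_pattern_d_no_fungal(taxonomy):
    bact = [_bact(i) for i in range(12)]
    nwk = f"(({_ladder(bact[:6])},{_pez(0)}),{_ladder(bact[6:])});"
    call = classify_pattern(parse_newick(nwk, focal_id=_pez(0)), taxonomy, CFG)
    assert call.topology_pattern == TopologyPattern.D_NO_FUNGAL
    assert call.focal_patch == (_pez(0),)


def test_classify_uninformative_tiny_tree(taxonomy):
    nwk = f"({_pez(0)},({_bact(0)},{_bact(1)}));"
    call = classify_pattern(parse_newick(nwk, focal_id=_pez(0)), taxonomy, CFG)
    assert call.topology_pattern == TopologyPattern.UNINFORMATIVE


def test_classify_outside_fungal_leaves_force_vertical(taxonomy):
    # single-class focal clan, but another fungal leaf elsewhere in the tree
    fungi = [_pez(i) for i in range(4)]
    stray = "Sordariomycetes_o1f1g1_sp1"
    bact = [_bact(i) for i in range(6)]
    nwk = (
        f"(({_ladder(bact[:3])},{_ladder(fungi)}),"
        f"(({stray},{_bact(6)}),{_ladder(bact[3:6])}));"
    )
    call = classify_pattern(parse_newick(nwk, focal_id=fungi[0]), taxonomy, CFG)
    assert call.topology_pattern == TopologyPattern.B_VERTICAL
    assert call.outside_fungal_count == 1


def test_classify_too_few_donors_is_uninformative(taxonomy):
    fungi = [_pez(i) for i in range(4)]
    bact = [_bact(0), _bact(1)]  # below min_donor_leaves=3
    nwk = f"({_ladder(fungi)},({bact[0]},{bact[1]}));"
    call = classify_pattern(parse_newick(nwk, focal_id=fungi[0]), taxonomy, CFG)
    assert call.topology_pattern == TopologyPattern.UNINFORMATIVE


def test_classify_nonfungal_focal_errors(taxonomy):
    nwk = f"(({_bact(0)},{_bact(1)}),({_bact(2)},{_bact(3)}));"
    with pytest.raises(ValueError, match="focal"):
        classify_pattern(parse_newick(nwk, focal_id=_bact(0)), taxonomy, CFG)


# ---------------------------------------------------------------------------
# invariances


def test_classification_invariant_to_rooting(taxonomy):
    spec = ScenarioSpec(
        id="inv-a", planted_pattern=TopologyPattern.A_HGT,
        planted_contamination="none",
        params={"n_focal_patch": 4, "n_outside_fungal": 0, "n_donor": 10},
        seed=99,
    )
    tree = generate_tree(spec, taxonomy)
    baseline = classify_pattern(tree, taxonomy, CFG, candidate_id="x")
    rng = random.Random(1)
    dt = tree.dendropy_tree
    nodes = [n for n in dt.preorder_node_iter() if n.parent_node is not None]
    for node in rng.sample(nodes, 5):
        clone = dendropy.Tree(tree.dendropy_tree)
        target = clone.find_node(lambda n: n.leaf_nodes() and
                                 {l.taxon.label for l in n.leaf_nodes()} ==
                                 {l.taxon.label for l in node.leaf_nodes()})
        clone.reroot_at_edge(target.edge, update_bipartitions=False)
        rerooted = parse_newick(
            clone.as_string(schema="newick", suppress_rooting=True,
                            unquoted_underscores=True),
            focal_id=tree.focal_id,
        )
        call = classify_pattern(rerooted, taxonomy, CFG, candidate_id="x")
        assert call.topology_pattern == baseline.topology_pattern
        assert call.focal_patch == baseline.focal_patch


def test_classification_invariant_to_leaf_relabeling(taxonomy):
    from hgtscan.taxonomy import TaxonomyTable

    spec = ScenarioSpec(
        id="inv-c", planted_pattern=TopologyPattern.C_ANCIENT,
        planted_contamination="none",
        params={"n_focal_patch": 4, "n_outside_fungal": 0, "n_donor": 9},
        seed=123,
    )
    tree = generate_tree(spec, taxonomy)
    baseline = classify_pattern(tree, taxonomy, CFG, candidate_id="x")
    mapping = {leaf: f"z{i:03d}" for i, leaf in enumerate(sorted(tree.leaf_ids))}
    clone = dendropy.Tree(tree.dendropy_tree)
    for leaf in clone.leaf_node_iter():
        leaf.taxon.label = mapping[leaf.taxon.label]
    relabeled = GeneTree(clone, mapping[tree.focal_id])
    moved = TaxonomyTable({mapping[k]: taxonomy[k] for k in tree.leaf_ids})
    call = classify_pattern(relabeled, moved, CFG, candidate_id="x")
    assert call.topology_pattern == baseline.topology_pattern
    assert call.focal_patch == tuple(sorted(mapping[x] for x in baseline.focal_patch))


# ---------------------------------------------------------------------------
# finalize_call


@pytest.mark.parametrize(
    "pattern, verdict, expected",
    [
        (TopologyPattern.A_HGT, None, FinalCall.HGT),
        (TopologyPattern.A_HGT, Verdict.CLEAN, FinalCall.HGT),
        (TopologyPattern.A_HGT, Verdict.CONTAMINATED, FinalCall.CONTAMINATION),
        (TopologyPattern.D_NO_FUNGAL, Verdict.CLEAN, FinalCall.HGT),
        (TopologyPattern.D_NO_FUNGAL, Verdict.CONTAMINATED, FinalCall.CONTAMINATION),
        (TopologyPattern.D_NO_FUNGAL, Verdict.INDETERMINATE, FinalCall.CONTAMINATION),
        (TopologyPattern.B_VERTICAL, None, FinalCall.VERTICAL),
        (TopologyPattern.B_VERTICAL, Verdict.CONTAMINATED, FinalCall.VERTICAL),
        (TopologyPattern.C_ANCIENT, None, FinalCall.ANCIENT_TRANSFER_OR_LOSS),
        (TopologyPattern.UNINFORMATIVE, None, FinalCall.UNINFORMATIVE),
    ],
)
def test_finalize_call_mapping(pattern, verdict, expected):
    call = PatternCall(candidate_id="c", topology_pattern=pattern)
    assert finalize_call(call, verdict).final_call == expected


def test_finalize_never_hgt_for_b_c_uninformative():
    for pattern in (TopologyPattern.B_VERTICAL, TopologyPattern.C_ANCIENT,
                    TopologyPattern.UNINFORMATIVE):
        for verdict in (None, Verdict.CLEAN, Verdict.CONTAMINATED):
            call = PatternCall(candidate_id="c", topology_pattern=pattern)
            assert finalize_call(call, verdict).final_call != FinalCall.HGT


def test_finalize_d_without_verdict_errors():
    call = PatternCall(candidate_id="c", topology_pattern=TopologyPattern.D_NO_FUNGAL)
    with pytest.raises(ValueError, match="verdict"):
        finalize_call(call, None)


def test_finalize_indeterminate_rescue_flag():
    call = PatternCall(candidate_id="c", topology_pattern=TopologyPattern.D_NO_FUNGAL)
    out = finalize_call(call, Verdict.INDETERMINATE, indeterminate_is_clean=True)
    assert out.final_call == FinalCall.HGT


# ---------------------------------------------------------------------------
# transfer-node mapping


def _mrca_oracle(tree, labels):
    """Path-intersection: deepest node common to all root-to-leaf paths."""
    paths = []
    for label in labels:
        node = tree.find_node_with_taxon_label(label)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths.append(list(reversed(path)))
    deepest = None
    for nodes in zip(*paths):
        if len({id(n) for n in nodes}) == 1:
            deepest = nodes[0]
        else:
            break
    return deepest


def test_infer_transfer_node_examples(taxonomy):
    st = species_tree_from_taxonomy(taxonomy)
    sp = "Pezizomycotina_o1f1g1_sp1"
    assert node_label(infer_transfer_node(st, [sp])) == sp
    # two species of the same genus -> genus node
    node = infer_transfer_node(st, [sp, "Pezizomycotina_o1f1g1_sp2"])
    assert node_label(node) == "Pezizomycotina_o1f1g1"
    # species spanning two classes -> phylum node
    node = infer_transfer_node(st, [sp, "Sordariomycetes_o2f1g2_sp1"])
    assert node_label(node) == "Ascomycota"
    with pytest.raises(ValueError, match="Unknown_sp"):
        infer_transfer_node(st, [sp, "Unknown_sp"])
    with pytest.raises(ValueError):
        infer_transfer_node(st, [])


def test_infer_transfer_node_matches_path_intersection_oracle():
    rng = random.Random(17)
    labels = [f"sp{i:02d}" for i in range(50)]
    gene = _random_gene_tree(rng, 50, labels=labels)
    st = SpeciesTree(gene.dendropy_tree)
    for _ in range(40):
        subset = rng.sample(labels, rng.randint(1, 8))
        got = infer_transfer_node(st, subset)
        expected = _mrca_oracle(st.dendropy_tree, subset)
        assert got is expected
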