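"""Distance computation, neighbor joining, quartet assembly, RF distance."""

import itertools

import dendropy
import numpy as np
import pytest

import radintro as ri
from radintro.trees import tree_bipartitions
from oracles import brute_force_p_distance, brute_force_rf


def test_p_distance_worked_examples():
    dm = ri.p_distance({"a": "ACGT", "b": "ACGT"})
    assert dm.d[0, 1] == 0.0
    dm = ri.p_distance({"a": "ACGT", "b": "ACGA"})
    assert dm.d[0, 1] == 0.25
    # heterozygote vs matching homozygote counts half a difference
    dm = ri.p_distance({"a": "AAAA", "b": "AAAR"})
    assert dm.d[0, 1] == 0.125


def test_p_distance_excludes_n_and_gaps_pairwise():
    dm = ri.p_distance({"a": "ACNT-A", "b": "ACGTTA"})
    # comparable: positions 0,1,3,5 (N and '-' excluded); all matching
    assert dm.d[0, 1] == 0.0
    assert dm.n_sites[0, 1] == 4
    with pytest.raises(ValueError, match="no comparable"):
        ri.p_distance({"a": "NN", "b": "AC"})


@pytest.mark.parametrize("seed", range(10))
def test_p_distance_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    chars = list("ACGTRYSWKMN-")
    seqs = {
        f"t{i}": "".join(rng.choice(chars, size=30)) for i in range(4)
    }
    try:
        dm = ri.p_distance(seqs)
    except ValueError:
        return
    for i, j in itertools.combinations(range(4), 2):
        exp = brute_force_p_distance(seqs[f"t{i}"], seqs[f"t{j}"])
        assert dm.d[i, j] == pytest.approx(exp)


def test_nj_three_taxa_solves_three_point_equations():
    labels = ["a", "b", "c"]
    d = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
    tree = ri.neighbor_joining(ri.DistanceMatrix(labels, d, np.ones((3, 3))))
    dists = {}
    pdm = tree.phylogenetic_distance_matrix()
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        dists[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    assert dists[frozenset(("a", "b"))] == pytest.approx(3.0)
    assert dists[frozenset(("a", "c"))] == pytest.approx(4.0)
    assert dists[frozenset(("b", "c"))] == pytest.approx(5.0)


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
    labels = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    # four-point condition: two of the three pair sums are equal and maximal
    sums = sorted([d[0, 1] + d[2, 3], d[0, 2] + d[1, 3], d[0, 3] + d[1, 2]])
    assert sums[1] == sums[2] and sums[0] < sums[1]
    tree = ri.neighbor_joining(ri.DistanceMatrix(labels, d, np.ones((4, 4))))
    assert tree_bipartitions(tree) == {frozenset(("A", "B"))}
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, j in itertools.combinations(range(4), 2):
        assert pdm.distance(taxa[labels[i]], taxa[labels[j]]) == pytest.approx(
            d[i, j]
        )


def _random_additive(rng, n):
    """Random binary tree with positive lengths and its path distances."""
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=__import__("random").Random(int(rng.integers(1 << 30))),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i}"
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(0.1, 2.0))
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in labels}
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return tree, labels, d


@pytest.mark.parametrize("seed", range(8))
def test_nj_consistency_on_random_additive_matrices(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    true_tree, labels, d = _random_additive(rng, n)
    nj = ri.neighbor_joining(ri.DistanceMatrix(labels, d, np.ones((n, n))))
    assert ri.rf_distance(nj, true_tree) == 0


def test_nj_agrees_with_skbio_on_additive_input():
    import skbio

    rng = np.random.default_rng(77)
    n = 7
    _, labels, d = _random_additive(rng, n)
    ours = ri.neighbor_joining(ri.DistanceMatrix(labels, d, np.ones((n, n))))
    sk = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
    theirs = dendropy.Tree.get(data=str(sk), schema="newick", preserve_underscores=True)
    assert ri.rf_distance(ours, theirs) == 0


def test_nj_invariant_to_taxon_order():
    rng = np.random.default_rng(3)
    _, labels, d = _random_additive(rng, 6)
    base = ri.neighbor_joining(ri.DistanceMatrix(labels, d, np.ones((6, 6))))
    perm = [3, 1, 5, 0, 4, 2]
    labels2 = [labels[i] for i in perm]
    d2 = d[np.ix_(perm, perm)]
    other = ri.neighbor_joining(ri.DistanceMatrix(labels2, d2, np.ones((6, 6))))
    assert ri.rf_distance(base, other) == 0


# -- RF ------------------------------------------------------------------


def test_rf_identical_and_alternative_resolutions():
    a = dendropy.Tree.get(data="((A,B),(C,D),E);", schema="newick", preserve_underscores=True)
    b = dendropy.Tree.get(data="((A,B),(C,D),E);", schema="newick", preserve_underscores=True)
    assert ri.rf_distance(a, b) == 0
    # two resolutions of a five-taxon group differing in one grouping each
    gg = dendropy.Tree.get(data="(((A,B),C),(D,E));", schema="newick", preserve_underscores=True)
    gg_alt = dendropy.Tree.get(data="(((A,C),B),(D,E));", schema="newick", preserve_underscores=True)
    assert ri.rf_distance(gg, gg_alt) == 2


def test_rf_maximal_on_six_taxa():
    a = dendropy.Tree.get(data="(((A,B),(C,D)),(E,F));", schema="newick", preserve_underscores=True)
    b = dendropy.Tree.get(data="(((A,F),(C,E)),(B,D));", schema="newick", preserve_underscores=True)
    assert ri.rf_distance(a, b) == 2 * (6 - 3)


def test_rf_leaf_set_mismatch_raises():
    a = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick", preserve_underscores=True)
    b = dendropy.Tree.get(data="((A,B),(C,E));", schema="newick", preserve_underscores=True)
    with pytest.raises(ValueError, match="leaf sets"):
        ri.rf_distance(a, b)


@pytest.mark.parametrize("seed", range(8))
def test_rf_matches_dendropy_oracle(seed):
    rng = np.random.default_rng(200 + seed)
    n = int(rng.integers(4, 10))
    t1 = _random_additive(rng, n)[0]
    t2 = _random_additive(rng, n)[0]
    nw1 = t1.as_string(schema="newick", unquoted_underscores=True)
    nw2 = t2.as_string(schema="newick", unquoted_underscores=True)
    assert ri.rf_distance(t1, t2) == brute_force_rf(nw1, nw2)
    # and against dendropy's own symmetric difference
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=nw1, schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=nw2, schema="newick", taxon_namespace=tns)
    a.is_rooted = False
    b.is_rooted = False
    a.update_bipartitions()
    b.update_bipartitions()
    assert ri.rf_distance(t1, t2) == dendropy.calculate.treecompare.symmetric_difference(a, b)


# -- quartet species tree ------------------------------------------------


def test_quartet_tree_unanimous_gene_trees():
    gt = "((a1,b1),(c1,(d1,e1)));"
    taxa = {f"{s}1": s.upper() for s in "abcde"}
    tree, details = ri.quartet_species_tree(
        [gt] * 10, taxa_map=taxa, return_details=True
    )
    expect = dendropy.Tree.get(data="((A,B),(C,(D,E)));", schema="newick", preserve_underscores=True)
    assert ri.rf_distance(tree, expect) == 0
    assert all(
        max(t.values()) == sum(t.values()) for t in details["tallies"].values()
    )
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and not node.is_leaf():
            assert node.label == "100"


def test_quartet_tree_majority_resolution_wins():
    trees = ["((A,B),(C,D));"] * 6 + ["((A,C),(B,D));"] * 2 + ["((A,D),(B,C));"] * 2
    tree = ri.quartet_species_tree(trees)
    assert tree_bipartitions(tree) == {frozenset(("A", "B"))}


def test_quartet_tree_recovers_msc_species_tree():
    model = ri.SpeciesTreeModel(
        "((((A:1,B:1):0.5,C:1.5):0.5,D:2):0.5,E:2.5);", samples_per_species=1
    )
    gene_trees = ri.simulate_gene_trees(model, 2000, seed=21)
    newicks = [gt.newick() for gt in gene_trees]
    taxa = {f"{s}_1.a": s for s in "ABCDE"}
    taxa.update({f"{s}_1.b": s for s in "ABCDE"})
    # one haplotype per species: restrict via taxa_map on .a tips only
    pruned = []
    for gt in gene_trees:
        t = dendropy.Tree.get(data=gt.newick(), schema="newick", preserve_underscores=True)
        keep = [lf.taxon for lf in t.leaf_node_iter() if lf.taxon.label.endswith(".a")]
        t.retain_taxa(keep)
        pruned.append(t)
    tree = ri.quartet_species_tree(
        pruned, taxa_map={f"{s}_1.a": s for s in "ABCDE"}
    )
    expect = dendropy.Tree.get(
        data="((((A,B),C),D),E);", schema="newick"
    )
    assert ri.rf_distance(tree, expect) == 0


def test_quartet_tree_invariant_to_input_order():
    trees = ["((A,B),(C,D));"] * 5 + ["((A,C),(B,D));"] * 2
    t1 = ri.quartet_species_tree(trees)
    t2 = ri.quartet_species_tree(list(reversed(trees)))
    assert ri.rf_distance(t1, t2) == 0


def test_quartet_tree_warns_on_uninformative_quartet():
    # D and E never co-occur in a gene tree, so quartets containing both
    # are uninformative and excluded with a warning
    trees = ["((A,B),(C,D));"] * 3 + ["((A,B),(C,E));"] * 3
    with pytest.warns(UserWarning, match="no informative gene tree"):
        tree = ri.quartet_species_tree(trees)
    assert frozenset(("A", "B")) in tree_bipartitions(tree)


def test_quartet_tree_needs_four_species():
    with pytest.raises(ValueError, match="four species"):
        ri.quartet_species_tree(["((A,B),C);"])


# -- bootstrap support ---------------------------------------------------


def _consistent_locus_set():
    from conftest import locus_set_from_consensus

    rows = []
    for _ in range(5):
        rows.append(
            {
                "A_1": "AAAAAAAA",
                "B_1": "AAAAAAAC",
                "C_1": "GGGGAAAA",
                "D_1": "GGGGAAGA",
            }
        )
    return locus_set_from_consensus(rows)


def test_bootstrap_support_consistent_signal_is_100():
    ls = _consistent_locus_set()
    for unit in ("site", "locus"):
        tree = ri.bootstrap_support(ls, n_reps=30, unit=unit, seed=1)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and not node.is_leaf():
                assert node.label == "100"


def test_bootstrap_single_replicate_support_is_binary():
    ls = _consistent_locus_set()
    tree = ri.bootstrap_support(ls, n_reps=1, unit="site", seed=5)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and not node.is_leaf():
            assert node.label in ("0", "100")


def test_bootstrap_support_stable_across_seeds():
    model = ri.SpeciesTreeModel(
        "((((A:1,B:1):1,C:2):1,D:3):1,E:4);", samples_per_species=1
    )
    ls = ri.simulate_dataset(model, 60, theta=0.05, seed=8)
    t1 = ri.bootstrap_support(ls, n_reps=300, unit="site", seed=1)
    t2 = ri.bootstrap_support(ls, n_reps=300, unit="site", seed=2)
    s1 = {
        frozenset(lf.taxon.label for lf in nd.leaf_iter()): int(nd.label)
        for nd in t1.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf()
    }
    s2 = {
        frozenset(lf.taxon.label for lf in nd.leaf_iter()): int(nd.label)
        for nd in t2.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf()
    }
    common = set(s1) & set(s2)
    assert common
    for key in common:
        assert abs(s1[key] - s2[key]) <= 8
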