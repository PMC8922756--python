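import itertools
import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from plastidscape.alignment import GeneAlignment
from plastidscape.genetrees import (
    DistanceMatrix,
    bootstrap_supports,
    collapse_low_support,
    distance_matrix,
    estimate_species_tree,
    nj_tree,
    prune_to_shared,
    quartet_score,
    read_newick,
    rf_distance,
    splits,
    splits_with_support,
    star_tree,
    tip_labels,
    write_newick,
)
from plastidscape.simulate import simulate_alignment, simulate_gene_trees, simulate_species_tree

FIVE_TAXA = list("ABCDE")


def all_five_taxon_topologies():
    """The 15 unrooted binary topologies on 5 tips, as newick strings."""
    out = []
    # unrooted binary on 5 taxa: pick the cherry pair {x,y} and the tip z
    # attached to the internal edge -> ((x,y),w,(z,v)) enumerations
    seen = set()
    for pair in itertools.combinations(FIVE_TAXA, 2):
        rest = [t for t in FIVE_TAXA if t not in pair]
        for pair2 in itertools.combinations(rest, 2):
            single = [t for t in rest if t not in pair2][0]
            key = frozenset([frozenset(pair), frozenset(pair2)])
            if key in seen:
                continue
            seen.add(key)
            out.append(f"(({pair[0]},{pair[1]}),{single},({pair2[0]},{pair2[1]}));")
    assert len(out) == 15
    return out


def dendropy_rf(n1: str, n2: str) -> int:
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2)


def test_rf_identical_zero():
    t = read_newick("((A,B),(C,D));")
    assert rf_distance(t, read_newick("((A,B),(C,D));")) == 0


def test_rf_four_taxa_alternatives():
    t1 = read_newick("((A,B),(C,D));")
    t2 = read_newick("((A,C),(B,D));")
    assert rf_distance(t1, t2) == 2
    assert rf_distance(t1, t2, normalized=True) == pytest.approx(1.0)


def test_rf_matches_dendropy_on_all_five_taxon_pairs():
    tops = all_five_taxon_topologies()
    for n1, n2 in itertools.combinations_with_replacement(tops, 2):
        got = rf_distance(read_newick(n1), read_newick(n2))
        assert got == dendropy_rf(n1, n2)


def test_rf_is_metric_on_five_taxon_trees():
    tops = [read_newick(n) for n in all_five_taxon_topologies()]
    d = [[rf_distance(a, b) for b in tops] for a in tops]
    for i in range(15):
        assert d[i][i] == 0
        for j in range(15):
            assert d[i][j] == d[j][i]
            if i != j:
                assert d[i][j] > 0
            for k in range(15):
                assert d[i][k] <= d[i][j] + d[j][k]


def test_rf_tip_mismatch_error_lists_labels():
    t1 = read_newick("((A,B),(C,D));")
    t2 = read_newick("((A,B),(C,E));")
    with pytest.raises(ValueError, match="D"):
        rf_distance(t1, t2)


def test_prune_to_shared():
    t1 = read_newick("((A,B),((C,D),E));")
    t2 = read_newick("((A,C),(B,(D,X)));")
    p1, p2 = prune_to_shared(t1, t2)
    assert tip_labels(p1) == tip_labels(p2) == ["A", "B", "C", "D"]
    rf_distance(p1, p2)  # must not raise


def test_rf_random_eight_taxon_pairs_vs_oracle():
    rng = np.random.default_rng(7)
    labels = [f"t{i}" for i in range(1, 9)]
    for _ in range(20):
        n1 = make_random_newick(labels, rng)
        n2 = make_random_newick(labels, rng)
        assert rf_distance(read_newick(n1), read_newick(n2)) == dendropy_rf(n1, n2)


def make_random_newick(labels, rng):
    items = list(labels)
    rng.shuffle(items)
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b})")
    return "(" + ",".join(items) + ");"


# ------------------------------------------------------------- distances
def test_distance_identical_rows_zero():
    aln = GeneAlignment("g", ["a", "b", "c"], ["ACGT" * 5] * 3)
    dm = distance_matrix(aln)
    assert np.allclose(dm.matrix, 0)


def test_jc69_closed_form():
    # p = 0.1 -> d = -(3/4) ln(1 - 4*0.1/3)
    rows = ["A" * 10, "A" * 9 + "C", "A" * 10]
    aln = GeneAlignment("g", ["a", "b", "c"], rows)
    dm = distance_matrix(aln, "JC69")
    assert dm.value("a", "b") == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
    assert dm.value("a", "b") == pytest.approx(0.107326, abs=1e-6)


def test_distance_matches_naive_recount():
    rng = np.random.default_rng(1)
    rows = ["".join(rng.choice(list("ACGT-N"), size=60)) for _ in range(4)]
    aln = GeneAlignment("g", list("abcd"), rows)
    dm = distance_matrix(aln, "p")
    for (i, a), (j, b) in itertools.combinations(enumerate(rows), 2):
        comp = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
        want = sum(x != y for x, y in comp) / len(comp)
        assert dm.matrix[i, j] == pytest.approx(want)


def test_saturated_pair_infinite():
    aln = GeneAlignment("g", ["a", "b", "c"], ["AAAA", "CCCC", "AAAA"])
    dm = distance_matrix(aln, "JC69")
    assert math.isinf(dm.value("a", "b"))


def test_nj_additive_recovery():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
    labels = list("ABCD")
    mat = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 0, 0],
        ],
        dtype=float,
    )
    mat[3, 2] = mat[2, 3] = 7
    mat[3, 3] = 0
    tree = nj_tree(DistanceMatrix(labels, mat))
    assert splits(tree) == {frozenset({"C", "D"})}
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(mat[i, j])


def test_nj_three_taxa_closed_form():
    mat = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(list("ABC"), mat))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    assert pdm.patristic_distance(taxa["A"], taxa["B"]) == pytest.approx(3)
    assert pdm.patristic_distance(taxa["A"], taxa["C"]) == pytest.approx(4)
    assert pdm.patristic_distance(taxa["B"], taxa["C"]) == pytest.approx(5)


def test_nj_taxon_order_invariance():
    rng = np.random.default_rng(2)
    tree0 = simulate_species_tree(6, 0)
    aln = simulate_alignment(tree0, 500, 0.4, 0.1, seed=1, name="g")
    dm = distance_matrix(aln)
    base = splits(nj_tree(dm))
    perm = list(rng.permutation(len(dm.labels)))
    dm2 = DistanceMatrix([dm.labels[i] for i in perm], dm.matrix[np.ix_(perm, perm)])
    assert splits(nj_tree(dm2)) == base


def test_nj_infinite_entries_error_names_pair():
    mat = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
    with pytest.raises(ValueError, match="A.*B"):
        nj_tree(DistanceMatrix(list("ABC"), mat))


def test_nj_convergence_with_length():
    wrong = 0
    for s in range(10):
        tree = simulate_species_tree(8, 100 + s)
        short = simulate_alignment(tree, 200, 0.4, 0.08, seed=s, name="s")
        long = simulate_alignment(tree, 5000, 0.4, 0.08, seed=s, name="l")
        rf_short = rf_distance(nj_tree(distance_matrix(short)), tree)
        rf_long = rf_distance(nj_tree(distance_matrix(long)), tree)
        assert rf_long <= rf_short or rf_long == 0
        wrong += rf_long > 0
    assert wrong <= 2  # long alignments essentially always recover the topology


# ------------------------------------------------------------- bootstrap
def test_bootstrap_deterministic():
    tree = simulate_species_tree(6, 5)
    aln = simulate_alignment(tree, 400, 0.4, 0.1, seed=2, name="g")
    t1 = bootstrap_supports(aln, n_reps=50, seed=9)
    t2 = bootstrap_supports(aln, n_reps=50, seed=9)
    assert splits_with_support(t1) == splits_with_support(t2)


def test_bootstrap_clean_data_high_support():
    tree = simulate_species_tree(6, 5)
    aln = simulate_alignment(tree, 4000, 0.4, 0.1, seed=2, name="g")
    t = bootstrap_supports(aln, n_reps=100, seed=1)
    sups = [s for s in splits_with_support(t).values() if s is not None]
    assert sups and all(s >= 95 for s in sups)


def test_bootstrap_identical_rows_star():
    aln = GeneAlignment("g", ["a", "b", "c", "d"], ["ACGT" * 10] * 4)
    t = bootstrap_supports(aln, n_reps=10, seed=0)
    assert splits(t) == frozenset()


# ------------------------------------------------------------- collapse
def test_collapse_none_below_threshold():
    t = read_newick("((A,B)90,((C,D)50,E)40);", support_scale="bootstrap")
    out = collapse_low_support(t, 33)
    assert splits(out) == splits(t)


def test_collapse_all_star():
    t = read_newick("((A,B)10,((C,D)5,E)2);", support_scale="bootstrap")
    out = collapse_low_support(t, 33)
    assert splits(out) == frozenset()


def test_collapse_single_edge_polytomy():
    # trifurcating root so each internal node carries a distinct unrooted edge
    t = read_newick("((A,B)20,(C,D)80,E);", support_scale="bootstrap")
    out = collapse_low_support(t, 33)
    assert frozenset({"C", "D"}) in splits(out)
    assert len(splits(out)) == 1  # AB edge gone -> degree-4 polytomy
    # rf to original equals the number of collapsed edges
    assert rf_distance(out, t) == 1


def test_collapse_probability_scale():
    t = read_newick("((A,B)0.2,((C,D)0.9,E)0.8);", support_scale="probability")
    out = collapse_low_support(t, 33)
    assert frozenset({"A", "B"}) not in splits(out)
    assert frozenset({"C", "D"}) in splits(out)


def test_collapse_requires_scale():
    t = read_newick("((A,B)20,(C,D));")
    with pytest.raises(ValueError):
        collapse_low_support(t, 33)


def test_collapse_never_adds_bipartitions():
    for seed in range(5):
        tree = simulate_species_tree(7, seed)
        aln = simulate_alignment(tree, 300, 0.4, 0.05, seed=seed, name="g")
        t = bootstrap_supports(aln, n_reps=30, seed=seed)
        out = collapse_low_support(t, 70)
        assert splits(out) <= splits(t)


# ------------------------------------------------------------- quartets
def test_quartet_score_simple():
    ab_cd = read_newick("((A,B),(C,D));")
    ac_bd = read_newick("((A,C),(B,D));")
    assert quartet_score(ab_cd, [ab_cd, ab_cd, ac_bd]) == 2
    est = estimate_species_tree([ab_cd, ab_cd, ac_bd])
    assert splits(est) == {frozenset({"C", "D"})}
    assert est.quartet_score == 2


def test_species_tree_identical_inputs():
    t = read_newick("((A,B),((C,D),E));")
    est = estimate_species_tree([t, t, t])
    assert splits(est) == splits(t)
    assert all(s == pytest.approx(1.0) for s in splits_with_support(est).values())


def test_exhaustive_refuses_large():
    trees = [simulate_species_tree(10, s) for s in range(2)]
    with pytest.raises(ValueError, match="greedy"):
        estimate_species_tree(trees, mode="exhaustive")


def test_species_tree_recovery_seven_taxa():
    # one-gene regimes give each perturbed gene an independent SPR draw
    ok = 0
    for seed in range(20):
        sp = simulate_species_tree(7, seed)
        regimes = [(1, 0)] * 3 + [(1, 1)] * 3
        gts = simulate_gene_trees(sp, regimes, seed=seed)
        est = estimate_species_tree(gts, mode="exhaustive")
        ok += rf_distance(est, sp) == 0
    assert ok >= 18


def test_greedy_matches_exhaustive_small():
    for seed in range(5):
        sp = simulate_species_tree(7, seed)
        gts = simulate_gene_trees(sp, [(4, 0), (2, 2)], seed=seed)
        ex = estimate_species_tree(gts, mode="exhaustive")
        gr = estimate_species_tree(gts, mode="greedy-NNI")
        assert gr.quartet_score <= ex.quartet_score
        assert gr.quartet_score >= 0.9 * ex.quartet_score


def test_newick_support_roundtrip():
    t = read_newick("((A,B)88,((C,D)45,E)67);", support_scale="bootstrap")
    text = write_newick(t)
    back = read_newick(text, support_scale="bootstrap")
    assert splits_with_support(back) == splits_with_support(t)


def test_star_tree_no_splits():
    assert splits(star_tree(list("ABCDE"))) == frozenset()
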