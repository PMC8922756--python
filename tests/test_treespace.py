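import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from plastidscape.alignment import GeneAlignment
from plastidscape.genetrees import DistanceMatrix, read_newick, rf_distance, splits
from plastidscape.simulate import simulate_alignment, simulate_gene_trees, simulate_species_tree
from plastidscape.treespace import (
    cluster_concatenate_and_retree,
    cluster_property_report,
    find_clusters,
    gene_discordance,
    pcoa,
    tree_distance_matrix,
)


def _regime_setup(seed, n_taxa=10, regimes=((8, 0), (8, 4))):
    sp = simulate_species_tree(n_taxa, seed)
    gts = simulate_gene_trees(sp, list(regimes), seed=seed)
    sp.gene_name = "species"
    return sp, gts


# --------------------------------------------------------------- distances
def test_matrix_of_identical_trees_zero():
    t = read_newick("((A,B),(C,D));")
    copies = [read_newick("((A,B),(C,D));") for _ in range(4)]
    dm = tree_distance_matrix(copies)
    assert np.allclose(dm.matrix, 0)


def test_matrix_matches_pairwise_calls():
    sp, gts = _regime_setup(0)
    dm = tree_distance_matrix(gts)
    for i, a in enumerate(gts):
        for j, b in enumerate(gts):
            if i < j:
                assert dm.matrix[i, j] == rf_distance(a, b)
    assert np.allclose(dm.matrix, dm.matrix.T)
    assert np.allclose(np.diag(dm.matrix), 0)


# --------------------------------------------------------------- pcoa
def test_pcoa_zero_matrix():
    dm = DistanceMatrix(list("abc"), np.zeros((3, 3)))
    emb = pcoa(dm)
    assert emb.coordinates.shape[1] == 0
    assert emb.negative_magnitude == 0


def test_pcoa_collinear_points():
    d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
    emb = pcoa(DistanceMatrix(list("abc"), d))
    assert emb.coordinates.shape[1] == 1
    x = emb.coordinates[:, 0]
    assert abs(x[0] - x[2]) == pytest.approx(2)
    assert abs(x[0] - x[1]) == pytest.approx(1)


def test_pcoa_reconstructs_euclidean_input():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(5, 2))
    d = squareform(pdist(pts))
    emb = pcoa(DistanceMatrix([f"p{i}" for i in range(5)], d))
    rec = squareform(pdist(emb.coordinates))
    assert np.abs(rec - d).max() < 1e-9
    assert emb.negative_magnitude < 1e-9


def test_pcoa_proportions_sum_le_one():
    sp, gts = _regime_setup(1)
    emb = pcoa(tree_distance_matrix(gts))
    assert emb.proportion.sum() <= 1 + 1e-12
    assert np.all(np.diff(emb.eigenvalues) <= 1e-12)  # descending


def test_pcoa_input_order_invariance():
    sp, gts = _regime_setup(2)
    dm = tree_distance_matrix(gts)
    emb = pcoa(dm)
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(len(dm.labels)))
    dm2 = DistanceMatrix([dm.labels[i] for i in perm], dm.matrix[np.ix_(perm, perm)])
    emb2 = pcoa(dm2)
    # distances within the embedding agree regardless of input order
    d1 = squareform(pdist(emb.coordinates))
    d2 = squareform(pdist(emb2.coordinates))
    inv = np.argsort(perm)
    assert np.allclose(d2[np.ix_(inv, inv)], d1, atol=1e-8)


def test_pcoa_rejects_asymmetric():
    with pytest.raises(ValueError):
        pcoa(DistanceMatrix(list("ab"), np.array([[0.0, 1.0], [2.0, 0.0]])))


# --------------------------------------------------------------- clustering
def test_clusters_recover_regimes():
    sp, gts = _regime_setup(4, 12, ((10, 0), (10, 3), (10, 7)))
    dm = tree_distance_matrix(gts + [sp])
    cl = find_clusters(dm, exclude_labels=["species"])
    assert cl.k == 3
    planted = [g.regime for g in gts]
    got = [cl.assignment[g.gene_name] for g in gts]
    assert adjusted_rand_score(planted, got) >= 0.9
    assert "species" not in cl.assignment


def test_two_identical_regimes_not_forced_to_three():
    sp, gts = _regime_setup(5, 10, ((10, 0), (10, 0)))
    with pytest.warns(UserWarning):
        cl = find_clusters(tree_distance_matrix(gts))
    assert cl.k == 1  # all trees identical -> all distances zero


def test_cluster_order_invariance():
    sp, gts = _regime_setup(6, 10, ((8, 0), (8, 4)))
    dm = tree_distance_matrix(gts)
    cl1 = find_clusters(dm)
    rng = np.random.default_rng(1)
    perm = list(rng.permutation(len(dm.labels)))
    dm2 = DistanceMatrix([dm.labels[i] for i in perm], dm.matrix[np.ix_(perm, perm)])
    cl2 = find_clusters(dm2)
    # same partition up to relabeling
    lab1 = [cl1.assignment[l] for l in dm.labels]
    lab2 = [cl2.assignment[l] for l in dm.labels]
    assert adjusted_rand_score(lab1, lab2) == pytest.approx(1.0)


def test_clusters_need_enough_items():
    dm = DistanceMatrix(list("abcd"), np.ones((4, 4)) - np.eye(4))
    with pytest.raises(ValueError):
        find_clusters(dm, k_range=range(2, 9))


# --------------------------------------------------------------- GD
def test_gd_zero_for_identical_topology():
    sp, gts = _regime_setup(7, 10, ((6, 0), (6, 4)))
    emb = pcoa(tree_distance_matrix(gts + [sp]))
    gd = gene_discordance(emb, "species")
    for g in gts:
        if g.regime == 0:
            assert gd[g.gene_name] == pytest.approx(0, abs=1e-9)


def test_gd_matches_hand_computation():
    sp, gts = _regime_setup(8, 10, ((5, 0), (5, 3)))
    emb = pcoa(tree_distance_matrix(gts + [sp]))
    gd = gene_discordance(emb, "species")
    k = min(2, emb.coordinates.shape[1])
    ref = emb.coordinates[emb.labels.index("species"), :k]
    for g in gts:
        pt = emb.coordinates[emb.labels.index(g.gene_name), :k]
        assert gd[g.gene_name] == pytest.approx(float(np.linalg.norm(pt - ref)))


def test_gd_monotone_in_spr():
    highs, lows = [], []
    for seed in range(5):
        sp, gts = _regime_setup(20 + seed, 12, ((15, 1), (15, 4)))
        emb = pcoa(tree_distance_matrix(gts + [sp]))
        gd = gene_discordance(emb, "species")
        lows.append(np.mean([gd[g.gene_name] for g in gts if g.regime == 0]))
        highs.append(np.mean([gd[g.gene_name] for g in gts if g.regime == 1]))
    assert np.mean(highs) > np.mean(lows)


def test_gd_missing_reference():
    sp, gts = _regime_setup(9)
    emb = pcoa(tree_distance_matrix(gts))
    with pytest.raises(ValueError):
        gene_discordance(emb, "species")


# --------------------------------------------------------------- properties
def _prop_table(rng, shift_gc=0.0):
    rows = []
    for i in range(24):
        c = 1 if i < 12 else 2
        rows.append(
            {
                "gene": f"g{i}",
                "cluster": c,
                "gc": rng.normal(0.38 + (shift_gc if c == 2 else 0.0), 0.01),
                "aligned_length": rng.normal(800, 100),
                "pv": rng.normal(0.1, 0.02),
                "omega": rng.normal(0.2, 0.05),
            }
        )
    return pd.DataFrame(rows)


def test_property_report_medians_match_recompute():
    rng = np.random.default_rng(0)
    table = _prop_table(rng)
    summary, tests = cluster_property_report(table)
    for _, row in summary.iterrows():
        sub = table[table["cluster"] == row["cluster"]][row["property"]]
        assert row["median"] == pytest.approx(sub.median())


def test_property_report_type_one_error_rate():
    sig = 0
    for seed in range(50):
        table = _prop_table(np.random.default_rng(seed))
        _, tests = cluster_property_report(table)
        sig += int((tests[tests["property"] == "gc"]["p"] < 0.05).any())
    assert sig <= 10  # ~5% expected; allow generous margin


def test_property_report_power_on_shift():
    table = _prop_table(np.random.default_rng(1), shift_gc=0.03)  # +3 sigma
    _, tests = cluster_property_report(table)
    row = tests[tests["property"] == "gc"].iloc[0]
    assert row["p"] < 0.001 and row["stars"] == "***"


def test_property_report_singleton_excluded():
    rng = np.random.default_rng(2)
    table = _prop_table(rng)
    table.loc[len(table)] = {"gene": "solo", "cluster": 3, "gc": 0.4,
                             "aligned_length": 700, "pv": 0.1, "omega": 0.2}
    with pytest.warns(UserWarning):
        summary, tests = cluster_property_report(table)
    assert set(tests["cluster1"]) | set(tests["cluster2"]) == {1, 2}


# --------------------------------------------------------------- retree
def _alignments_for(gts, sp, length=500):
    alns = {}
    for i, g in enumerate(gts):
        alns[g.gene_name] = simulate_alignment(g, length, 0.4, 0.08, seed=i, name=g.gene_name)
    return alns


def test_single_cluster_tree_equals_concatenated():
    sp, gts = _regime_setup(10, 8, ((6, 0),))
    alns = _alignments_for(gts, sp)
    from plastidscape.treespace import ClusterAssignment

    assignment = ClusterAssignment({g.gene_name: 1 for g in gts}, 1, "manual")
    out = cluster_concatenate_and_retree(alns, assignment, {"species": sp})
    from plastidscape.genetrees import distance_matrix, nj_tree

    concat = GeneAlignment.concatenate([alns[g] for g in sorted(alns)])
    direct = nj_tree(distance_matrix(concat))
    assert rf_distance(out[1]["tree"], direct) == 0


def test_low_discordance_cluster_closest_to_species():
    sp, gts = _regime_setup(11, 10, ((8, 0), (8, 5)))
    alns = _alignments_for(gts, sp, length=2000)
    from plastidscape.treespace import ClusterAssignment

    assignment = ClusterAssignment(
        {g.gene_name: g.regime + 1 for g in gts}, 2, "planted"
    )
    out = cluster_concatenate_and_retree(alns, assignment, {"species": sp})
    assert out[1]["rf_to_reference"]["species"] < out[2]["rf_to_reference"]["species"]


def test_gene_order_permutation_invariant():
    sp, gts = _regime_setup(12, 8, ((5, 0),))
    alns = _alignments_for(gts, sp)
    from plastidscape.treespace import ClusterAssignment

    a1 = ClusterAssignment({g.gene_name: 1 for g in gts}, 1, "m")
    a2 = ClusterAssignment({g.gene_name: 1 for g in reversed(gts)}, 1, "m")
    t1 = cluster_concatenate_and_retree(alns, a1)[1]["tree"]
    t2 = cluster_concatenate_and_retree(alns, a2)[1]["tree"]
    assert splits(t1) == splits(t2)
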