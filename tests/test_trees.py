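"""UPGMA/NJ construction, bootstrap supports, collapse, Newick round trips."""

import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from ssrdup.matrix import BandMatrix, MISSING
from ssrdup.distances import pairwise_differences
from ssrdup.trees import (
    TreeError,
    bootstrap_support,
    collapse_branches,
    neighbor_joining,
    to_newick,
    upgma,
)

from conftest import distance_result, random_additive_tree, random_band_matrix


def test_upgma_two_step_hand_example():
    """d(A,B)=2, d(A,C)=d(B,C)=8: A,B join at height 1, root at height 4."""
    D = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]])
    t = upgma(distance_result(["A", "B", "C"], D))
    depths = t.root_to_leaf_depths()
    assert all(d == pytest.approx(4.0) for d in depths.values())
    ab = next(
        nd
        for nd in t.tree.preorder_node_iter()
        if not nd.is_leaf() and nd.parent_node is not None
    )
    assert {lf.taxon.label for lf in ab.leaf_iter()} == {"A", "B"}
    assert ab.child_nodes()[0].edge.length == pytest.approx(1.0)


def test_upgma_rejects_asymmetric_input():
    d = distance_result(["A", "B", "C"], np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]]))
    d.diff_counts = d.diff_counts.copy()
    d.diff_counts[0, 1] = 3
    with pytest.raises(TreeError, match="symmetric"):
        upgma(d)


def test_upgma_equal_distances_collapse_to_polytomy_heights():
    D = np.full((4, 4), 6)
    np.fill_diagonal(D, 0)
    t = upgma(distance_result(list("ABCD"), D))
    # all internal heights equal, so internal edges have zero length
    internal = [
        nd
        for nd in t.tree.preorder_node_iter()
        if not nd.is_leaf() and nd.parent_node is not None
    ]
    assert all(nd.edge.length == pytest.approx(0.0) for nd in internal)


@pytest.mark.parametrize("seed", range(6))
def test_upgma_is_ultrametric(seed):
    d = pairwise_differences(random_band_matrix(seed, n=6 + seed, m=25))
    t = upgma(d)
    depths = list(t.root_to_leaf_depths().values())
    assert max(depths) - min(depths) < 1e-9
    assert t.leaf_labels() == set(d.accession_ids)


def test_upgma_recovers_ultrametric_heights():
    """On distances generated from an ultrametric tree, merge heights match."""
    # three clusters at heights 1, 2; root at 5
    labels = list("ABCD")
    H = {("A", "B"): 2, ("C", "D"): 4}
    D = np.zeros((4, 4))
    for i, j in itertools.combinations(range(4), 2):
        a, b = labels[i], labels[j]
        D[i, j] = D[j, i] = H.get((a, b), 10)
    t = upgma(distance_result(labels, D))
    depths = t.root_to_leaf_depths()
    assert depths["A"] == pytest.approx(5.0)
    pdm = t.tree.phylogenetic_distance_matrix()
    tns = t.tree.taxon_namespace
    assert pdm.distance(tns.get_taxon("A"), tns.get_taxon("B")) == pytest.approx(2.0)
    assert pdm.distance(tns.get_taxon("C"), tns.get_taxon("D")) == pytest.approx(4.0)


def test_upgma_matches_scipy_average_linkage():
    """Cophenetic distances equal scipy's average-linkage cophenetic matrix."""
    from scipy.cluster.hierarchy import average, cophenet
    from scipy.spatial.distance import squareform

    d = pairwise_differences(random_band_matrix(11, n=9, m=30, missing_rate=0))
    t = upgma(d)
    coph = squareform(cophenet(average(squareform(d.diff_counts.astype(float)))))
    pdm = t.tree.phylogenetic_distance_matrix()
    tns = t.tree.taxon_namespace
    for i, j in itertools.combinations(range(d.n), 2):
        mine = pdm.distance(
            tns.get_taxon(d.accession_ids[i]), tns.get_taxon(d.accession_ids[j])
        )
        assert mine == pytest.approx(coph[i, j])


def test_nj_three_leaves_closed_form():
    D = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]])
    t = neighbor_joining(distance_result(["A", "B", "C"], D))
    lengths = {
        lf.taxon.label: lf.edge.length for lf in t.tree.leaf_node_iter()
    }
    assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0), "C": pytest.approx(7.0)}


def test_nj_needs_three_leaves():
    with pytest.raises(TreeError):
        neighbor_joining(distance_result(["A", "B"], np.array([[0, 2], [2, 0]])))


@pytest.mark.parametrize("seed,n_leaves", [(s, n) for s in range(4) for n in (4, 8, 12)])
def test_nj_exact_recovery_on_additive_distances(seed, n_leaves):
    """NJ recovers topology and branch lengths of a random additive tree."""
    true_tree, labels, D, tns = random_additive_tree(n_leaves, seed)
    t = neighbor_joining(distance_result(labels, D))
    assert t.log["clamped_negative_length"] == 0
    mine = dendropy.Tree.get(
        data=to_newick(t), schema="newick", taxon_namespace=tns
    )
    for tr in (true_tree, mine):
        tr.is_rooted = False
        tr.update_bipartitions()
    assert treecompare.symmetric_difference(true_tree, mine) == 0
    pdm = mine.phylogenetic_distance_matrix()
    for i, j in itertools.combinations(range(n_leaves), 2):
        got = pdm.distance(tns.get_taxon(labels[i]), tns.get_taxon(labels[j]))
        assert got == pytest.approx(D[i, j])


def test_nj_star_distances_deterministic():
    D = np.full((5, 5), 4.0)
    np.fill_diagonal(D, 0)
    d = distance_result(list("ABCDE"), D)
    assert to_newick(neighbor_joining(d)) == to_newick(neighbor_joining(d))


def test_nj_matches_skbio_on_additive_distances():
    """Independent implementation cross-check on clean additive input."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    _, labels, D, tns = random_additive_tree(9, seed=42)
    mine = dendropy.Tree.get(
        data=to_newick(neighbor_joining(distance_result(labels, D))),
        schema="newick",
        taxon_namespace=tns,
    )
    other = dendropy.Tree.get(
        data=str(skbio_nj(DistanceMatrix(D, labels))),
        schema="newick",
        taxon_namespace=tns,
    )
    for tr in (mine, other):
        tr.is_rooted = False
        tr.update_bipartitions()
    assert treecompare.symmetric_difference(mine, other) == 0


def test_nj_clamps_negative_branch_lengths():
    # strongly non-additive: one point far off the metric
    D = np.array(
        [
            [0, 1, 10, 10],
            [1, 0, 10, 2],
            [10, 10, 0, 10],
            [10, 2, 10, 0],
        ],
        dtype=float,
    )
    t = neighbor_joining(distance_result(list("ABCD"), D))
    for nd in t.tree.preorder_node_iter():
        if nd.parent_node is not None:
            assert nd.edge.length >= 0
    assert t.log["clamped_negative_length"] >= 0


# ---------------------------------------------------------------------------
# bootstrap


def _clean_two_clade_matrix():
    """Two blocks of identical fingerprints: unanimous support signal."""
    row_a = [1, 1, 1, 0, 0, 0, 1, 0, 1, 0]
    row_b = [0, 0, 0, 1, 1, 1, 0, 1, 0, 1]
    cells = np.array([row_a, row_a, row_a, row_b, row_b, row_b], dtype=np.int8)
    return BandMatrix(
        [f"A{i}" for i in range(6)], [f"F{j}" for j in range(10)], cells
    )


def test_unanimous_signal_gives_full_support():
    m = _clean_two_clade_matrix()
    t = bootstrap_support(m, "upgma", n_replicates=30, seed=3)
    sup = t.supports()
    for clade in (frozenset({"A0", "A1", "A2"}), frozenset({"A3", "A4", "A5"})):
        assert sup[clade] == pytest.approx(100.0)


def test_single_replicate_supports_are_zero_or_hundred():
    m = random_band_matrix(2, n=6, m=15)
    t = bootstrap_support(m, "upgma", n_replicates=1, seed=9)
    vals = [v for v in t.supports().values() if v is not None]
    assert vals and all(v in (0.0, 100.0) for v in vals)


@pytest.mark.parametrize("method", ["upgma", "nj"])
def test_bootstrap_deterministic_under_seed(method):
    m = random_band_matrix(4, n=7, m=20)
    t1 = bootstrap_support(m, method, n_replicates=25, seed=11)
    t2 = bootstrap_support(m, method, n_replicates=25, seed=11)
    assert t1.supports() == t2.supports()
    assert to_newick(t1) == to_newick(t2)


def test_bootstrap_supports_invariant_to_row_order():
    """Same seed stream over columns: supports do not depend on row order.

    Holds for tie-free distances; index-based tie-breaking is deliberately
    deterministic rather than permutation-invariant, so the input here has
    all pairwise distances distinct by construction (disjoint one-segments
    of length 4**i give Sidon-like distances 4**i + 4**j).
    """
    sizes = [1, 4, 16, 64, 256, 1024]
    cells = np.zeros((6, sum(sizes)), dtype=np.int8)
    start = 0
    for i, a in enumerate(sizes):
        cells[i, start : start + a] = 1
        start += a
    m = BandMatrix(
        [f"A{i}" for i in range(6)], [f"F{j}" for j in range(sum(sizes))], cells
    )
    s1 = bootstrap_support(m, "upgma", n_replicates=40, seed=5).supports()
    for pseed in range(3):
        perm = np.random.default_rng(pseed).permutation(m.n_accessions)
        mp = BandMatrix(
            [m.accession_ids[i] for i in perm], m.fragment_ids, m.cells[perm]
        )
        s2 = bootstrap_support(mp, "upgma", n_replicates=40, seed=5).supports()
        assert s1 == s2


def test_bootstrap_redraws_zero_overlap_replicates():
    # one column pair-scored only: resampling without column 0 orphans the pair
    cells = np.array(
        [[1, 1, MISSING], [0, MISSING, 1], [1, 0, 1], [0, 1, 0]], dtype=np.int8
    )
    m = BandMatrix(["A", "B", "C", "D"], ["F0", "F1", "F2"], cells)
    t = bootstrap_support(m, "upgma", n_replicates=20, seed=0)
    assert t.log["redrawn_replicates"] > 0
    assert t.n_replicates == 20


# ---------------------------------------------------------------------------
# collapse + newick


def _supported_toy():
    D = np.array(
        [
            [0, 2, 8, 8, 12, 12],
            [2, 0, 8, 8, 12, 12],
            [8, 8, 0, 4, 12, 12],
            [8, 8, 4, 0, 12, 12],
            [12, 12, 12, 12, 0, 2],
            [12, 12, 12, 12, 2, 0],
        ],
        dtype=float,
    )
    t = upgma(distance_result(list("ABCDEF"), D))
    supports = {
        frozenset("AB"): 95.0,
        frozenset("CD"): 40.0,
        frozenset("ABCD"): 80.0,
        frozenset("EF"): 99.0,
    }
    for nd in t.supported_nodes():
        nd.support = supports[frozenset(lf.taxon.label for lf in nd.leaf_iter())]
    return t


def test_collapse_removes_only_weak_bipartitions():
    t = _supported_toy()
    collapsed = collapse_branches(t, 75.0)
    kept = {
        frozenset(lf.taxon.label for lf in nd.leaf_iter())
        for nd in collapsed.supported_nodes()
    }
    assert kept == {frozenset("AB"), frozenset("ABCD"), frozenset("EF")}
    assert collapsed.leaf_labels() == set("ABCDEF")
    # surviving supports unchanged
    assert collapsed.supports()[frozenset("AB")] == 95.0
    # original untouched
    assert frozenset("CD") in t.supports()


def test_collapse_identity_when_all_strong():
    t = _supported_toy()
    for nd in t.supported_nodes():
        nd.support = 90.0
    assert to_newick(collapse_branches(t, 75.0)) == to_newick(t)


def test_collapse_all_weak_gives_star():
    t = _supported_toy()
    for nd in t.supported_nodes():
        nd.support = 10.0
    star = collapse_branches(t, 75.0)
    assert star.supported_nodes() == []
    assert len(star.tree.seed_node.child_nodes()) == 6


def test_newick_round_trip_isomorphism():
    t = _supported_toy()
    nwk = to_newick(t)
    tns = t.tree.taxon_namespace
    back = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=tns)
    # serialisation does not pin the rooting state; compare unrooted shapes
    for tr in (t.tree, back):
        tr.is_rooted = False
        tr.update_bipartitions()
    assert treecompare.symmetric_difference(t.tree, back) == 0
    assert ":1.0" in nwk  # branch lengths serialised
    assert "95" in nwk  # supports as internal labels


def test_newick_two_leaf_shape():
    D = np.array([[0, 4], [4, 0]])
    nwk = to_newick(upgma(distance_result(["A", "B"], D)))
    assert nwk.strip() == "(A:2.0,B:2.0);"


def test_collapsed_polytomy_serialises_multifurcation():
    t = _supported_toy()
    star = collapse_branches(t, 1000.0)
    nwk = to_newick(star)
    # six leaves directly under the root
    assert nwk.count(",") == 5 and nwk.count("(") == 1
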