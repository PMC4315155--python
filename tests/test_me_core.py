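"""OLS branch lengths, tree length, and the exact insertion scan."""

import numpy as np
import pytest

from meplace import me_core
from meplace.me_core import (
    PlacementEngine,
    best_placement,
    insertion_scan,
    ols_branch_lengths,
    oracle_insertion_cost,
    tree_length,
)
from meplace.seqio import Topology, parse_newick_string

from _helpers import (
    additive_matrix,
    lstsq_branch_lengths,
    pauplin_length,
    random_distance_matrix,
    random_topology,
    pauplin_length as _pauplin,
)

QUARTET = "((a:1,b:1):1,(c:1,d:1):1);"


def quartet_additive():
    topo = parse_newick_string(QUARTET)
    order = ["a", "b", "c", "d"]
    # pendant lengths 1, internal 1: d_ab = d_cd = 2, cross pairs = 3
    D = np.array(
        [
            [0, 2, 3, 3],
            [2, 0, 3, 3],
            [3, 3, 0, 2],
            [3, 3, 2, 0],
        ],
        dtype=float,
    )
    return topo, D, order


class TestBranchLengths:
    def test_quartet_additive_recovery(self):
        topo, D, order = quartet_additive()
        bl = ols_branch_lengths(topo, D, order)
        by_split = {frozenset(topo.split_of_edge(e)): bl[e] for e in range(5)}
        for leaf in "abcd":
            assert by_split[frozenset({leaf})] == pytest.approx(1.0)
        internal = next(v for k, v in by_split.items() if len(k) == 2)
        assert internal == pytest.approx(1.0)

    def test_star_like_quartet(self):
        topo = parse_newick_string(QUARTET)
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        bl = ols_branch_lengths(topo, D, ["a", "b", "c", "d"])
        by_split = {frozenset(topo.split_of_edge(e)): bl[e] for e in range(5)}
        for leaf in "abcd":
            assert by_split[frozenset({leaf})] == pytest.approx(1.0)
        internal = next(v for k, v in by_split.items() if len(k) == 2)
        assert internal == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generating_lengths_on_additive_matrix(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            topo = random_topology(8, rng)
            order, D = additive_matrix(topo)
            bl = ols_branch_lengths(topo, D, order)
            assert np.allclose(bl, topo.edge_lengths(), atol=1e-9)

    def test_matches_least_squares_on_nonadditive_data(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = int(rng.integers(5, 11))
            topo = random_topology(n, rng)
            D = random_distance_matrix(n, rng)
            bl = ols_branch_lengths(topo, D, topo.leaf_labels)
            ref = lstsq_branch_lengths(topo, D, topo.leaf_labels)
            assert np.allclose(bl, ref, atol=1e-10)

    def test_balanced_total_is_pauplin(self):
        rng = np.random.default_rng(12)
        topo = random_topology(7, rng)
        D = random_distance_matrix(7, rng)
        got = tree_length(topo, D, topo.leaf_labels, balanced=True)
        assert got == pytest.approx(
            pauplin_length(topo, D, topo.leaf_labels), abs=1e-10
        )


class TestTreeLength:
    def test_quartet_value(self):
        topo, D, order = quartet_additive()
        assert tree_length(topo, D, order) == pytest.approx(5.0)

    def test_linearity_in_distances(self):
        rng = np.random.default_rng(13)
        topo = random_topology(7, rng)
        D = random_distance_matrix(7, rng)
        s1 = tree_length(topo, D, topo.leaf_labels)
        s2 = tree_length(topo, 2.0 * D, topo.leaf_labels)
        assert s2 == pytest.approx(2.0 * s1)

    def test_equals_sum_of_lengths(self):
        rng = np.random.default_rng(14)
        topo = random_topology(9, rng)
        D = random_distance_matrix(9, rng)
        assert tree_length(topo, D, topo.leaf_labels) == pytest.approx(
            ols_branch_lengths(topo, D, topo.leaf_labels).sum()
        )

    def test_clamp_negative_option(self):
        rng = np.random.default_rng(15)
        topo = random_topology(8, rng)
        D = random_distance_matrix(8, rng)  # noisy: some negative estimates
        bl = ols_branch_lengths(topo, D, topo.leaf_labels)
        assert tree_length(
            topo, D, topo.leaf_labels, clamp_negative=True
        ) == pytest.approx(np.maximum(bl, 0).sum())


class TestOracle:
    def test_read_identical_to_leaf_adds_nothing(self):
        rng = np.random.default_rng(16)
        topo = random_topology(7, rng)
        order, D = additive_matrix(topo)
        x = order[3]
        d_r = D[3].copy()  # read sits exactly at leaf x
        e = topo.find_edge_by_split({x})
        cost = oracle_insertion_cost(topo, D, d_r, e, order)
        assert cost == pytest.approx(tree_length(topo, D, order), abs=1e-9)

    def test_all_edges_finite_on_quartet(self):
        topo, D, order = quartet_additive()
        costs = [oracle_insertion_cost(topo, D, [1, 2, 3, 2], e, order) for e in range(5)]
        assert np.isfinite(costs).all()

    def test_leaf_order_permutation_invariance(self):
        rng = np.random.default_rng(17)
        topo = random_topology(6, rng)
        D = random_distance_matrix(6, rng)
        d_r = rng.uniform(0.1, 1.0, 6)
        order = topo.leaf_labels
        perm = rng.permutation(6)
        order2 = [order[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        d2 = d_r[perm]
        for e in range(topo.n_edges):
            assert oracle_insertion_cost(topo, D, d_r, e, order) == pytest.approx(
                oracle_insertion_cost(topo, D2, d2, e, order2)
            )


class TestInsertionScan:
    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            n = int(rng.integers(5, 13))
            topo = random_topology(n, rng)
            D = random_distance_matrix(n, rng)
            d_r = rng.uniform(0.1, 1.0, n)
            scan = insertion_scan(topo, D, d_r, topo.leaf_labels)
            for e in range(topo.n_edges):
                want = oracle_insertion_cost(topo, D, d_r, e, topo.leaf_labels)
                assert scan.S[e] == pytest.approx(want, rel=1e-9)

    def test_additive_consistency_recovers_true_edge(self):
        # build an (n+1)-leaf model tree, hide one leaf, and check that the
        # scan puts it back with the model tree's total length
        rng = np.random.default_rng(19)
        for _ in range(5):
            full = random_topology(9, rng)
            order, Dfull = additive_matrix(full)
            x = order[4]
            k = order.index(x)
            pruned, truth = full.prune_leaf(x)
            keep = [i for i in range(len(order)) if i != k]
            order2 = [order[i] for i in keep]
            D = Dfull[np.ix_(keep, keep)]
            d_r = Dfull[k, keep]
            scan = insertion_scan(pruned, D, d_r, order2)
            e, s_min = best_placement(scan)
            assert e == truth
            assert s_min == pytest.approx(full.edge_lengths().sum(), abs=1e-9)

    def test_constant_shift_preserves_argmin(self):
        rng = np.random.default_rng(20)
        topo = random_topology(8, rng)
        D = random_distance_matrix(8, rng)
        d_r = rng.uniform(0.2, 1.0, 8)
        base = insertion_scan(topo, D, d_r, topo.leaf_labels)
        for c in (0.1, 0.5):
            shifted = insertion_scan(topo, D, d_r + c, topo.leaf_labels)
            assert np.argmin(shifted.S) == np.argmin(base.S)
            # verify against the brute-force scan of the shifted problem
            for e in range(topo.n_edges):
                want = oracle_insertion_cost(topo, D, d_r + c, e, topo.leaf_labels)
                assert shifted.S[e] == pytest.approx(want, rel=1e-9)

    def test_balanced_scan_matches_pauplin_oracle(self):
        rng = np.random.default_rng(21)
        topo = random_topology(8, rng)
        D = random_distance_matrix(8, rng)
        d_r = rng.uniform(0.1, 1.0, 8)
        scan = insertion_scan(topo, D, d_r, topo.leaf_labels, balanced=True)
        for e in range(topo.n_edges):
            grown = topo.insert_on_edge(e, "__q__")
            D2 = np.zeros((9, 9))
            D2[:8, :8] = D
            D2[8, :8] = D2[:8, 8] = d_r
            want = _pauplin(grown, D2, topo.leaf_labels + ["__q__"])
            assert scan.S[e] == pytest.approx(want, rel=1e-9)

    def test_attachment_pendant_matches_oracle_lengths(self):
        # at the best edge the pendant estimate must match the pendant OLS
        # length of the explicitly grown tree
        rng = np.random.default_rng(22)
        topo = random_topology(7, rng)
        order, D = additive_matrix(topo)
        d_r = D[2] + 0.07  # leaf 2 pushed away by a pendant of 0.07
        scan = insertion_scan(topo, D, d_r, order)
        e, _ = best_placement(scan)
        pend, dist, prox = scan.attachment(e)
        grown = topo.insert_on_edge(e, "__q__")
        D2 = np.zeros((8, 8))
        D2[:7, :7] = D
        D2[7, :7] = D2[:7, 7] = d_r
        bl = me_core.ols_branch_lengths(grown, D2, order + ["__q__"])
        pend_edge = grown.find_edge_by_split({"__q__"})
        assert pend == pytest.approx(bl[pend_edge], abs=1e-9)


class TestBestPlacement:
    def test_smallest_cost_wins(self):
        rng = np.random.default_rng(23)
        topo = random_topology(6, rng)
        D = random_distance_matrix(6, rng)
        scan = insertion_scan(topo, D, rng.uniform(0.1, 1, 6), topo.leaf_labels)
        e, s = best_placement(scan)
        assert s == scan.S.min()
        assert e == int(np.argmin(scan.S))

    def test_tie_breaks_to_smallest_edge(self):
        scan = me_core.InsertionScan(
            S=np.array([3.0, 1.0, 1.0, 2.0]), engine=None, read_averages=None
        )
        assert scan.best() == (1, 1.0)
        scan2 = me_core.InsertionScan(
            S=np.ones(4), engine=None, read_averages=None
        )
        assert scan2.best()[0] == 0


class TestEngineReuse:
    def test_one_build_for_many_reads(self):
        rng = np.random.default_rng(24)
        topo = random_topology(8, rng)
        D = random_distance_matrix(8, rng)
        before = PlacementEngine.build_count
        eng = PlacementEngine(topo, D, topo.leaf_labels)
        for _ in range(5):
            eng.scan(rng.uniform(0.1, 1.0, 8))
        assert PlacementEngine.build_count == before + 1
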