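import itertools

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst
from scipy.stats import ks_2samp

from mstgsa import (
    DistanceMatrix,
    PhenotypeLabels,
    build_mst,
    euclidean_distances,
    gsa_test,
    hdp_rank,
    ks_mst_stat,
    n_statistic,
    permutation_pvalue,
    ww_mst_stat,
)
from mstgsa.core_io import GeneSetCollection
from mstgsa.normalization import ExpressionMatrix


def labels_of(mask):
    mask = np.asarray(mask, dtype=bool)
    return PhenotypeLabels(
        [f"s{i}" for i in range(mask.size)],
        np.where(mask, "X", "Y"),
        group_order=("X", "Y"),
    )


def dm_from_1d(points):
    pts = np.asarray(points, dtype=float)[None, :]
    return euclidean_distances(pts)


# ---------------------------------------------------------------------------
# distances


class TestEuclideanDistances:
    def test_identical_columns_zero(self):
        d = euclidean_distances(np.array([[1.0, 1.0], [2.0, 2.0]]))
        assert d.values[0, 1] == 0.0

    def test_three_four_five(self):
        d = euclidean_distances(np.array([[0.0, 3.0], [0.0, 4.0]]))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_symmetry_enforced(self, rng):
        d = euclidean_distances(rng.normal(size=(5, 8)))
        np.testing.assert_allclose(d.values, d.values.T)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distances(np.array([[1.0]]))


# ---------------------------------------------------------------------------
# MST


def prufer_trees(n):
    """All labeled spanning trees on n nodes via Prüfer sequences."""
    if n == 2:
        return [np.array([[0, 1]])]
    trees = []
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = np.ones(n, dtype=int)
        for v in seq:
            degree[v] += 1
        edges = []
        seq = list(seq)
        leaves = sorted(i for i in range(n) if degree[i] == 1)
        for v in seq:
            leaf = leaves.pop(0)
            edges.append((leaf, v))
            degree[v] -= 1
            if degree[v] == 1:
                import bisect

                bisect.insort(leaves, v)
        edges.append((leaves[0], leaves[1]))
        trees.append(np.array(edges))
    return trees


class TestBuildMst:
    def test_path_through_sorted_1d_points(self):
        tree = build_mst(dm_from_1d([0.0, 1.0, 5.0]))
        assert sorted(map(tuple, tree.edges.tolist())) == [(0, 1), (1, 2)]
        assert tree.total_weight == pytest.approx(5.0)

    @pytest.mark.parametrize("n", [2, 4, 7])
    def test_edge_count(self, n, rng):
        tree = build_mst(euclidean_distances(rng.normal(size=(3, n))))
        assert tree.edges.shape == (n - 1, 2)

    def test_matches_brute_force_enumeration(self, rng):
        """Total weight equals the minimum over all Cayley-enumerated trees."""
        for n in (3, 4, 5, 6):
            trees = prufer_trees(n)
            for _ in range(30):
                d = euclidean_distances(rng.normal(size=(2, n)))
                mst = build_mst(d)
                best = min(d.values[t[:, 0], t[:, 1]].sum() for t in trees)
                assert mst.total_weight == pytest.approx(best)

    def test_matches_scipy_total_weight(self, rng):
        for _ in range(25):
            d = euclidean_distances(rng.normal(size=(4, 12)))
            ours = build_mst(d).total_weight
            theirs = scipy_mst(d.values).sum()
            assert ours == pytest.approx(theirs)

    def test_deterministic_under_ties(self):
        # four duplicated points: all distances zero, tree fixed by index order
        d = DistanceMatrix(np.zeros((4, 4)))
        tree = build_mst(d)
        assert tree.edges.tolist() == [[0, 1], [0, 2], [0, 3]]


# ---------------------------------------------------------------------------
# HDP ranking


class TestHdpRank:
    def test_path_follows_path_order(self):
        tree = hdp_rank(build_mst(dm_from_1d([0.0, 1.0, 2.0, 3.0])))
        assert tree.root == 0
        assert list(tree.hdp_ranks) == [0, 1, 2, 3]

    def test_1d_ranks_reproduce_sort_order(self, rng):
        for _ in range(20):
            points = rng.normal(size=9)
            tree = hdp_rank(build_mst(dm_from_1d(points)))
            by_rank = np.argsort(tree.hdp_ranks)
            walk = points[by_rank]
            assert np.all(np.diff(walk) > 0) or np.all(np.diff(walk) < 0)

    def test_star_root_is_a_leaf(self):
        # centre at origin, three leaves at distance 1: star MST
        pts = np.array([[0.0, 1.0, -1.0, 0.0], [0.0, 0.0, 0.0, 1.0]])
        tree = hdp_rank(build_mst(euclidean_distances(pts)))
        assert tree.root != 0  # the hub has eccentricity 1, leaves have 2
        assert tree.root == 1  # smallest-index tie-break among the leaves
        # all subtree heights below the hub tie; children by smallest index
        assert list(tree.hdp_ranks) == [1, 0, 2, 3]

    def test_ranks_are_a_bijection(self, rng):
        tree = hdp_rank(build_mst(euclidean_distances(rng.normal(size=(6, 11)))))
        assert sorted(tree.hdp_ranks) == list(range(11))


# ---------------------------------------------------------------------------
# statistics


class TestKsStat:
    def test_complete_separation(self):
        assert ks_mst_stat([0, 1, 2, 3], [True, True, False, False]) == 1.0

    def test_alternating(self):
        assert ks_mst_stat([0, 1, 2, 3], [True, False, True, False]) == 0.5

    def test_1d_equals_classical_ks(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(3, 9, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(0.4, 1.1, size=n2)
            points = np.concatenate([x, y])
            mask = np.arange(points.size) < n1
            tree = hdp_rank(build_mst(dm_from_1d(points)))
            ours = ks_mst_stat(tree.hdp_ranks, mask)
            classical = ks_2samp(x, y).statistic
            assert ours == pytest.approx(classical)


class TestWwStat:
    def test_two_blocks(self):
        tree = hdp_rank(build_mst(dm_from_1d([0.0, 1.0, 2.0, 3.0])))
        assert ww_mst_stat(tree, [True, True, False, False]) == 2.0

    def test_alternating(self):
        tree = hdp_rank(build_mst(dm_from_1d([0.0, 1.0, 2.0, 3.0])))
        assert ww_mst_stat(tree, [True, False, True, False]) == 4.0

    def test_1d_equals_classical_runs_count(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(3, 9, size=2)
            points = rng.normal(size=n1 + n2)
            mask = np.zeros(points.size, dtype=bool)
            mask[rng.choice(points.size, n1, replace=False)] = True
            tree = hdp_rank(build_mst(dm_from_1d(points)))
            ours = ww_mst_stat(tree, mask)
            sorted_labels = mask[np.argsort(points)]
            runs = 1 + np.sum(sorted_labels[1:] != sorted_labels[:-1])
            assert ours == runs


class TestNStatistic:
    def test_identical_multisets_zero(self):
        pts = np.array([[0.0, 1.0, 0.0, 1.0]])
        d = euclidean_distances(pts)
        assert n_statistic(d, [True, True, False, False]) == 0.0

    def test_singletons_hand_value(self):
        d = dm_from_1d([0.0, 2.0])
        assert n_statistic(d, [True, False]) == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self, rng):
        d = euclidean_distances(rng.normal(size=(5, 8)))
        mask = np.array([True] * 4 + [False] * 4)
        assert n_statistic(d, mask) == pytest.approx(n_statistic(d, ~mask))

    def test_translation_and_scale_behaviour(self, rng):
        values = rng.normal(size=(6, 10))
        mask = np.arange(10) < 5
        base = n_statistic(euclidean_distances(values), mask)
        shifted = n_statistic(euclidean_distances(values + 7.3), mask)
        scaled = n_statistic(euclidean_distances(values * 2.0), mask)
        assert shifted == pytest.approx(base)
        assert scaled == pytest.approx(base * np.sqrt(2.0))


def test_all_statistics_translation_invariant_scale_equivariant(rng):
    """Adding a constant never changes any statistic; positive scaling
    preserves the order of every statistic (KS and WW are exactly
    invariant, N scales monotonically), so permutation P-values are
    unaffected by either."""
    values = rng.normal(size=(6, 12))
    mask = np.arange(12) < 6
    for transform in (lambda v: v + 3.0, lambda v: v * 1.7):
        d0, d1 = euclidean_distances(values), euclidean_distances(transform(values))
        t0, t1 = hdp_rank(build_mst(d0)), hdp_rank(build_mst(d1))
        assert ks_mst_stat(t0.hdp_ranks, mask) == pytest.approx(
            ks_mst_stat(t1.hdp_ranks, mask))
        assert ww_mst_stat(t0, mask) == ww_mst_stat(t1, mask)


# ---------------------------------------------------------------------------
# permutation engine


class TestPermutationPvalue:
    def test_add_one_formula(self):
        from mstgsa.mst_tests import _pvalue_from_null

        null = np.linspace(0.0, 0.9, 999)  # all strictly below the observation
        assert _pvalue_from_null(1.0, null, "upper", "add-one") == pytest.approx(1 / 1000)
        assert _pvalue_from_null(1.0, null, "lower", "add-one") == pytest.approx(1.0)
        assert _pvalue_from_null(1.0, null, "upper", "strict") == 0.0

    def test_extreme_observation(self, labels10):
        # statistic maximal exactly for the observed split (or its mirror);
        # sampled relabelings reproduce it with probability 2/252 per draw
        def stat(mask):
            return float(np.all(mask == labels10.x_mask) or np.all(mask == ~labels10.x_mask))

        out = permutation_pvalue(stat, labels10, B=999, seed=1)
        assert 1 / 1000 <= out.pvalue <= 0.03

    def test_constant_statistic_p_one(self, labels10):
        out = permutation_pvalue(lambda mask: 1.0, labels10, B=200, seed=0)
        assert out.pvalue == 1.0

    def test_upper_tail_add_one_formula(self, labels10, rng):
        values = rng.normal(size=(4, 10))
        values[:, :5] += 3.0
        d = euclidean_distances(values)
        out = permutation_pvalue(
            lambda mask: n_statistic(d, mask), labels10, B=999, seed=3
        )
        # only redraws of the observed split (or its mirror) can tie it
        assert out.pvalue <= 0.03

    def test_doubling_B_is_consistent(self, labels10, rng):
        values = rng.normal(size=(4, 10))
        values[:, :5] += 0.8
        d = euclidean_distances(values)
        stat = lambda mask: n_statistic(d, mask)  # noqa: E731
        p1 = permutation_pvalue(stat, labels10, B=1000, seed=5).pvalue
        p2 = permutation_pvalue(stat, labels10, B=2000, seed=5).pvalue
        se = np.sqrt(p1 * (1 - p1) / 1000)
        assert abs(p1 - p2) < 3 * se + 2e-3

    def test_same_seed_reproduces(self, labels10, rng):
        values = rng.normal(size=(4, 10))
        d = euclidean_distances(values)
        stat = lambda mask: n_statistic(d, mask)  # noqa: E731
        a = permutation_pvalue(stat, labels10, B=300, seed=9)
        b = permutation_pvalue(stat, labels10, B=300, seed=9)
        assert a.pvalue == b.pvalue


# ---------------------------------------------------------------------------
# collection-level API


def make_em(values, provenance="rpkm+log2(1+x)"):
    g, s = values.shape
    return ExpressionMatrix(
        [f"g{i}" for i in range(g)], [f"s{j}" for j in range(s)], values,
        provenance, log_transformed=False,
    )


class TestGsaTest:
    def test_large_effect_detected_by_all_methods(self, rng):
        values = rng.normal(size=(16, 40))
        values[:, :20] += 2.0
        em = make_em(values)
        sets = GeneSetCollection({"hot": [f"g{i}" for i in range(16)]})
        labels = labels_of(np.arange(40) < 20)
        for method in ("KS", "WW", "N"):
            res = gsa_test(em, sets, labels, method, B=200, seed=4)
            assert res.loc[0, "pvalue"] < 0.05, method

    def test_missing_gene_names_set(self, rng):
        em = make_em(rng.normal(size=(4, 8)))
        sets = GeneSetCollection({"bad": ["g0", "nope"]})
        with pytest.raises(KeyError, match="bad"):
            gsa_test(em, sets, labels_of(np.arange(8) < 4), "N", B=10, seed=0)

    def test_results_independent_of_set_order(self, rng):
        em = make_em(rng.normal(size=(8, 12)))
        labels = labels_of(np.arange(12) < 6)
        genes = [f"g{i}" for i in range(8)]
        a = GeneSetCollection({"s1": genes[:4], "s2": genes[4:]})
        b = GeneSetCollection({"s2": genes[4:], "s1": genes[:4]})
        ra = gsa_test(em, a, labels, "KS", B=150, seed=8).set_index("set")
        rb = gsa_test(em, b, labels, "KS", B=150, seed=8).set_index("set")
        assert ra.loc["s1", "pvalue"] == rb.loc["s1", "pvalue"]
        assert ra.loc["s2", "pvalue"] == rb.loc["s2", "pvalue"]

    def test_sample_permutation_invariance(self, rng):
        """Relabeling the samples (columns and labels together) leaves the
        observed WW and N statistics exactly unchanged and the P-values
        within Monte-Carlo error.  (The KS statistic is excluded: the HDP
        traversal breaks subtree-height ties by node index, so its walk
        order is not relabeling-invariant.)"""
        values = rng.normal(size=(10, 14))
        values[:, :7] += 0.9
        mask = np.arange(14) < 7
        perm = rng.permutation(14)
        for method in ("WW", "N"):
            res0 = gsa_test(
                make_em(values), GeneSetCollection({"s": [f"g{i}" for i in range(10)]}),
                labels_of(mask), method, B=2000, seed=2,
            )
            resp = gsa_test(
                make_em(values[:, perm]),
                GeneSetCollection({"s": [f"g{i}" for i in range(10)]}),
                labels_of(mask[perm]), method, B=2000, seed=2,
            )
            assert res0.loc[0, "statistic"] == pytest.approx(resp.loc[0, "statistic"])
            p0, pp = res0.loc[0, "pvalue"], resp.loc[0, "pvalue"]
            se = np.sqrt(max(p0 * (1 - p0), 0.25 / 2000) / 2000)
            assert abs(p0 - pp) < 4 * se + 2e-3

    def test_null_rejection_rate_nominal(self, rng):
        """Exchangeable data: rejection fraction at alpha=0.05 within 3
        binomial SEs for the add-one estimator."""
        labels = labels_of(np.arange(20) < 10)
        n_sets = 150
        values = rng.normal(size=(8 * n_sets, 20))
        em = make_em(values)
        sets = GeneSetCollection({
            f"s{k}": [f"g{i}" for i in range(8 * k, 8 * (k + 1))]
            for k in range(n_sets)
        })
        res = gsa_test(em, sets, labels, "N", B=400, seed=11)
        rate = float((res["pvalue"] <= 0.05).mean())
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_sets)
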