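import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from stforge.errors import InvalidArgumentError
from stforge.metrics import (
    ContingencyTable,
    RankedLRSet,
    ari,
    csm,
    curve_cosine,
    nem,
    nmi,
    ripley_curves,
    ripley_l,
    rsi,
    same_type_edge_fraction,
    si,
    transition_discrepancy,
)
from stforge.patterns import transition_counts
from stforge.plate import NeighborGraph

PART_A = [0, 0, 0, 1, 1, 1]
PART_B = [0, 0, 1, 1, 1, 1]


class TestClusteringAgreement:
    def test_contingency_marginals(self):
        t = ContingencyTable.from_labels(PART_A, PART_B)
        assert np.array_equal(t.counts, [[2, 1], [0, 3]])
        assert np.array_equal(t.row_marginals, [3, 3])
        assert np.array_equal(t.col_marginals, [2, 4])
        assert t.total == 6

    def test_worked_example(self):
        # {a,b,c}{d,e,f} vs {a,b}{c,d,e,f}: (4 - 2.8) / (6.5 - 2.8)
        assert np.isclose(ari(PART_A, PART_B), (4 - 2.8) / (6.5 - 2.8))
        assert np.isclose(nmi(PART_A, PART_B), 0.47870397138568, atol=1e-10)

    def test_identity_and_permutation_invariance(self):
        assert ari(PART_A, PART_A) == 1.0
        assert nmi(PART_A, PART_A) == 1.0
        relabeled = [1 - x for x in PART_B]
        assert np.isclose(ari(PART_A, relabeled), ari(PART_A, PART_B))
        assert np.isclose(nmi(PART_A, relabeled), nmi(PART_A, PART_B))

    def test_matches_reference_implementation(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(10, 60)
            a = rng.integers(0, rng.integers(2, 6), n)
            b = rng.integers(0, rng.integers(2, 6), n)
            assert abs(ari(a, b) - sklearn_metrics.adjusted_rand_score(a, b)) < 1e-9
            assert (
                abs(nmi(a, b) - sklearn_metrics.normalized_mutual_info_score(a, b))
                < 1e-9
            )

    def test_independent_partitions_near_zero_nmi(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, 10000)
        b = rng.integers(0, 4, 10000)
        assert nmi(a, b) <= 0.01

    def test_trivial_single_cluster_pair(self):
        assert nmi([0, 0, 0], [1, 1, 1]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ari([0, 1], [0, 1, 2])


class TestTransitionDiscrepancy:
    def test_identical_datasets_zero(self, small_graph):
        labels = np.random.default_rng(0).integers(0, 3, small_graph.n_cells)
        d = transition_discrepancy((small_graph, labels), (small_graph, labels))
        assert d == 0.0

    def test_path_vs_identity_hand_value(self, path_graph_4):
        _plate, graph = path_graph_4
        d = transition_discrepancy((graph, np.array([0, 0, 1, 1])), np.eye(2))
        assert np.isclose(d, 2 / 3)

    def test_symmetry(self):
        a = np.array([[0.8, 0.2], [0.2, 0.8]])
        b = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert transition_discrepancy(a, b) == transition_discrepancy(b, a)


class TestCSM:
    def test_complete_graph_full_degree_centrality(self):
        n = 6
        adj = sp.csr_matrix(np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8))
        graph = NeighborGraph(adj, "knn", n - 1)
        out = csm(graph, np.array([0, 0, 1, 1, 2, 2]))
        assert np.allclose(out[:, 0], 1.0)

    def test_triangle_free_graph_zero_clustering(self, path_graph_4):
        _plate, graph = path_graph_4
        out = csm(graph, np.array([0, 0, 1, 1]))
        assert np.allclose(out[:, 1], 0.0)

    def test_bridged_triangles_hand_values(self, two_triangles):
        adj = two_triangles.adjacency.tolil()
        adj[2, 3] = adj[3, 2] = 1  # bridge
        graph = NeighborGraph(adj.tocsr(), "knn", 2)
        out = csm(graph, np.array([0, 0, 0, 1, 1, 1]))
        # 1 of the 3 non-members touches each group
        assert np.allclose(out[:, 0], 1 / 3)
        # member clustering: two pure-triangle nodes (cc=1), bridge node
        # has neighbors {two in-triangle, one across} with one edge -> 1/3
        assert np.allclose(out[:, 1], (1 + 1 + 1 / 3) / 3)
        # distances from each group to outsiders: 1, 2, 2
        assert np.allclose(out[:, 2], 3 / 5)

    def test_matches_networkx_group_centrality(self, small_graph):
        nx = pytest.importorskip("networkx")
        labels = np.random.default_rng(3).integers(0, 3, small_graph.n_cells)
        g = nx.from_scipy_sparse_array(small_graph.adjacency)
        out = csm(small_graph, labels)
        cc = nx.clustering(g)
        for t in range(3):
            members = np.flatnonzero(labels == t).tolist()
            assert np.isclose(out[t, 0], nx.group_degree_centrality(g, members))
            assert np.isclose(out[t, 1], np.mean([cc[m] for m in members]))
            assert np.isclose(out[t, 2], nx.group_closeness_centrality(g, members))

    def test_all_cells_one_type_flagged(self, two_triangles):
        with pytest.warns(UserWarning, match="owns all cells"):
            out = csm(two_triangles, np.zeros(6, dtype=int))
        assert np.isnan(out[0, 0]) and np.isnan(out[0, 2])


class TestNEM:
    def test_complete_graph_invariant_under_shuffles(self):
        n = 6
        adj = sp.csr_matrix(np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8))
        graph = NeighborGraph(adj, "knn", n - 1)
        z = nem(graph, np.array([0, 0, 0, 1, 1, 1]), n_perms=50, seed=0)
        assert np.allclose(z, 0.0)

    def test_exhaustive_null_matches_brute_force(self, two_triangles):
        labels = np.array([0, 0, 0, 1, 1, 1])
        z = nem(two_triangles, labels, method="exhaustive")
        # independent brute force over all C(6,3) = 20 balanced labelings
        A = two_triangles.adjacency
        samples = []
        for ones in itertools.combinations(range(6), 3):
            lab = np.zeros(6, dtype=int)
            lab[list(ones)] = 1
            samples.append(transition_counts(lab, A, 2))
        samples = np.stack(samples)
        x = transition_counts(labels, A, 2)
        mu, sd = samples.mean(axis=0), samples.std(axis=0)
        expected = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1), 0.0)
        assert np.abs(z - expected).max() < 1e-9

    def test_monte_carlo_agrees_with_exhaustive(self, two_triangles):
        labels = np.array([0, 0, 0, 1, 1, 1])
        z_ex = nem(two_triangles, labels, method="exhaustive")
        z_mc = nem(two_triangles, labels, n_perms=3000, seed=1)
        # the shuffle null samples the same distribution the exhaustive
        # null enumerates, so the seeded MC z-scores sit close to it
        assert np.abs(z_mc - z_ex).max() < 0.25

    def test_symmetric_for_symmetric_adjacency(self, small_graph):
        labels = np.random.default_rng(5).integers(0, 3, small_graph.n_cells)
        z = nem(small_graph, labels, n_perms=100, seed=2)
        assert np.allclose(z, z.T)


class TestJoinCount:
    def test_pure_components_give_one(self, two_triangles):
        assert same_type_edge_fraction(two_triangles, [0, 0, 0, 1, 1, 1]) == 1.0

    def test_alternating_path_gives_zero(self, path_graph_4):
        _plate, graph = path_graph_4
        assert same_type_edge_fraction(graph, [0, 1, 0, 1]) == 0.0


class TestRipley:
    def test_below_separation_distance_zero(self):
        coords = np.array([[0.2, 0.5], [0.8, 0.5]])  # separation 0.6
        L = ripley_l(coords, np.array([[0, 1], [0, 1]]), np.array([0.3, 0.5, 0.7]))
        assert np.array_equal(L[:2], [0.0, 0.0])
        assert L[2] > 0

    def test_csr_envelope_contains_baseline(self):
        """Pointwise 95% envelope of L(t) - t over CSR replicates straddles 0.

        Uses the border-corrected estimator: the uncorrected one is
        systematically biased low at larger t (points near the boundary
        see truncated neighborhoods), so only the corrected curve is
        comparable to the theoretical baseline.
        """
        rng = np.random.default_rng(0)
        t_grid = np.linspace(0.02, 0.2, 10)
        bounds = np.array([[0.0, 1.0], [0.0, 1.0]])
        devs = np.stack(
            [
                ripley_l(rng.uniform(size=(500, 2)), bounds, t_grid, "border") - t_grid
                for _ in range(99)
            ]
        )
        lo = np.percentile(devs, 2.5, axis=0)
        hi = np.percentile(devs, 97.5, axis=0)
        assert np.all(lo <= 0) and np.all(hi >= 0)

    def test_uncorrected_estimator_biased_low_at_range(self):
        # documents why the envelope test needs the border correction
        rng = np.random.default_rng(3)
        t_grid = np.array([0.2])
        bounds = np.array([[0.0, 1.0], [0.0, 1.0]])
        devs = [
            (ripley_l(rng.uniform(size=(500, 2)), bounds, t_grid) - t_grid)[0]
            for _ in range(30)
        ]
        assert np.mean(devs) < 0

    def test_clustered_points_exceed_baseline(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.3, 0.01, size=(100, 2))
        b = rng.normal(0.7, 0.01, size=(100, 2))
        coords = np.clip(np.vstack([a, b]), 0, 1)
        t_grid = np.array([0.05, 0.1])
        L = ripley_l(coords, np.array([[0, 1], [0, 1]]), t_grid)
        assert np.all(L > t_grid)

    def test_border_correction_runs(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(size=(200, 2))
        L = ripley_l(coords, np.array([[0, 1], [0, 1]]), np.array([0.05, 0.1]), "border")
        assert np.all(np.isfinite(L))

    def test_per_type_curves_and_baseline(self, cortex_fixture):
        t_grid = np.linspace(0.02, 0.2, 8)
        cs = ripley_curves(
            cortex_fixture.plate.coords, cortex_fixture.labels,
            cortex_fixture.plate.bounds, t_grid,
        )
        assert set(cs.curves) == set(np.unique(cortex_fixture.labels))
        assert np.array_equal(cs.csr_baseline, t_grid)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ripley_l(np.array([[0.5, 0.5]]), np.array([[0, 1], [0, 1]]), np.array([0.1]))


class TestCurveCosine:
    def test_identical_orthogonal_and_hand_value(self):
        assert np.isclose(curve_cosine([1.0, 2.0], [1.0, 2.0]), 1.0, rtol=1e-12)
        assert curve_cosine([1.0, 0.0], [0.0, 1.0]) == 0.0
        assert np.isclose(curve_cosine([1.0, 0.0], [1.0, 1.0]), 1 / np.sqrt(2))

    def test_zero_vector_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(curve_cosine([0.0, 0.0], [1.0, 1.0]))


class TestSetAgreement:
    def test_si_examples(self):
        assert si({"a", "b"}, {"a", "b"}) == 1.0
        assert si({"a"}, {"b"}) == 0.0
        assert si({1, 2, 3, 4}, {2, 3, 5, 6, 7, 8}) == 0.5

    def test_si_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            si(set(), {"a"})

    def test_rsi_identical_sets(self):
        a = RankedLRSet(["x", "y", "z"], [3.0, 2.0, 1.0])
        b = RankedLRSet(["x", "y", "z"], [30.0, 20.0, 10.0])
        assert rsi(a, b) == 1.0

    def test_rsi_hand_value(self):
        a = RankedLRSet(["p1", "p2"], [2.0, 1.0])
        b = RankedLRSet(["p1", "p2", "p3", "p4"], [4.0, 3.0, 2.0, 1.0])
        # 1 - ((|1/2 - 1/4| + |2/2 - 2/4|)) / 2 = 0.625
        assert rsi(a, b) == 0.625

    def test_rsi_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        pairs = [f"p{i}" for i in range(20)]
        a = RankedLRSet(pairs[:12], rng.random(12))
        b = RankedLRSet(pairs[5:], rng.random(15))
        assert np.isclose(rsi(a, b), rsi(b, a))
        assert rsi(a, b) <= 1.0

    def test_rsi_empty_overlap_flagged(self):
        a = RankedLRSet(["x"], [1.0])
        b = RankedLRSet(["y"], [1.0])
        with pytest.warns(UserWarning):
            assert np.isnan(rsi(a, b))

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            RankedLRSet(["x", "x"], [1.0, 2.0])
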