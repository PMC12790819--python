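import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from stforge import _sa
from stforge.assign import (
    AnnealSchedule,
    assign_celltypes,
    epoch_schedule,
    objective,
    recalibrate_proportions,
    target_counts,
    transition_frequency,
)
from stforge.errors import InvalidArgumentError
from stforge.patterns import PatternSpec, estimate_pattern, transition_counts
from stforge.plate import CellPlate, NeighborGraph, build_graph, generate_plate

SLOW_SCHEDULE = AnnealSchedule(
    n_epochs=1,
    zone_grid=(2, 2),
    initial_zone_dims=(0.5, 0.5),
    alpha=0.99,
    stall_limit=2000,
    max_temps=2000,
    moves_per_temp=100,
)


def _clique_pair(size=10):
    block = np.ones((size, size), dtype=np.int8) - np.eye(size, dtype=np.int8)
    adj = sp.block_diag([block, block]).tocsr()
    graph = NeighborGraph(adj, "knn", size - 1)
    coords = np.random.default_rng(0).uniform(size=(2 * size, 2))
    plate = CellPlate(coords, np.array([[0.0, 1.0], [0.0, 1.0]]))
    return graph, plate


class TestTransitionFrequency:
    def test_path_hand_count(self, path_graph_4):
        _plate, graph = path_graph_4
        T = transition_frequency(np.array([0, 0, 1, 1]), graph.adjacency)
        assert np.allclose(T, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]])

    def test_disconnected_components_give_identity(self, two_triangles):
        labels = np.array([0, 0, 0, 1, 1, 1])
        T = transition_frequency(labels, two_triangles.adjacency)
        assert np.array_equal(T, np.eye(2))

    def test_single_type(self, small_graph):
        T = transition_frequency(np.zeros(small_graph.n_cells, dtype=int), small_graph.adjacency)
        assert np.array_equal(T, [[1.0]])

    def test_onehot_matrix_input(self, path_graph_4):
        _plate, graph = path_graph_4
        X = np.eye(2)[[0, 0, 1, 1]]
        assert np.allclose(
            transition_frequency(X, graph.adjacency),
            transition_frequency(np.array([0, 0, 1, 1]), graph.adjacency),
        )

    def test_zero_row_flagged(self, two_triangles):
        # type 2 never occurs among neighbors of itself or anyone: absent type
        labels = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning):
            T = transition_frequency(labels, two_triangles.adjacency, n_types=3)
        assert np.array_equal(T[2], np.zeros(3))


class TestObjective:
    def test_exact_match_is_zero(self, path_graph_4):
        _plate, graph = path_graph_4
        P = np.array([[2 / 3, 1 / 3], [1 / 3, 2 / 3]])
        assert objective(np.array([0, 0, 1, 1]), graph.adjacency, P) == 0.0

    def test_identity_target_hand_value(self, path_graph_4):
        _plate, graph = path_graph_4
        val = objective(np.array([0, 0, 1, 1]), graph.adjacency, np.eye(2))
        assert np.isclose(val, 2 / 3)

    def test_self_consistency(self, small_graph):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, small_graph.n_cells)
        P = transition_frequency(labels, small_graph.adjacency)
        assert objective(labels, small_graph.adjacency, P) < 1e-12

    def test_dimension_mismatch_rejected(self, path_graph_4):
        _plate, graph = path_graph_4
        X = np.eye(2)[[0, 0, 1, 1]]  # one-hot with K=2 against a 3x3 target
        with pytest.raises(InvalidArgumentError):
            objective(X, graph.adjacency, np.eye(3))


class TestEpochSchedule:
    @pytest.mark.parametrize("n,expected", [(1000, 1), (16000, 3), (500, 1), (4000, 2)])
    def test_epoch_count(self, n, expected):
        assert epoch_schedule(n).n_epochs == expected

    def test_window_dims_shrink_to_initial(self):
        s = epoch_schedule(16000)
        dims = [s.window_dims(m) for m in range(1, s.n_epochs + 1)]
        assert all(a >= b for (a, _), (b, _) in zip(dims, dims[1:]))
        assert dims[-1] == s.initial_zone_dims

    def test_swaps_strictly_increase(self):
        s = epoch_schedule(16000)
        swaps = [s.swaps_per_move(m) for m in range(1, s.n_epochs + 1)]
        assert swaps == sorted(set(swaps))


class TestTargetCounts:
    def test_largest_remainder_with_ties(self):
        assert np.array_equal(target_counts([1 / 3, 1 / 3, 1 / 3], 10), [4, 3, 3])

    def test_sums_to_n(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pi = rng.dirichlet(np.ones(5))
            assert target_counts(pi, 137).sum() == 137


class TestTargetCountsProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        weights=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=8),
        n=st.integers(1, 500),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_apportionment_sums_and_stays_within_one_seat(self, weights, n):
        pi = np.asarray(weights) / np.sum(weights)
        counts = target_counts(pi, n)
        assert counts.sum() == n
        assert np.all(counts >= np.floor(pi * n))
        assert np.all(counts <= np.ceil(pi * n))


class TestRecalibrate:
    def test_forced_single_switch(self):
        labels = np.array([0, 0, 0, 1])
        out = recalibrate_proportions(labels, [2, 2], seed=0)
        assert np.array_equal(np.bincount(out), [2, 2])
        assert np.sum(out != labels) == 1  # only one surplus cell moved

    def test_noop_when_already_exact(self):
        labels = np.array([0, 1, 0, 1])
        out = recalibrate_proportions(labels, [2, 2], seed=0)
        assert np.array_equal(out, labels)

    def test_only_surplus_cells_relabeled(self):
        rng = np.random.default_rng(1)
        labels = rng.choice(3, 200, p=[0.6, 0.3, 0.1])
        targets = target_counts([1 / 3, 1 / 3, 1 / 3], 200)
        out = recalibrate_proportions(labels, targets, seed=5)
        assert np.array_equal(np.bincount(out, minlength=3), targets)
        changed = out != labels
        counts = np.bincount(labels, minlength=3)
        for t in range(3):
            if counts[t] <= targets[t]:  # deficient types never lose cells
                assert not np.any(changed & (labels == t))

    def test_infeasible_targets_rejected(self):
        with pytest.raises(InvalidArgumentError):
            recalibrate_proportions(np.array([0, 1]), [3, 1])


class TestIncrementalUpdates:
    def test_relabel_matches_full_recomputation(self, small_graph):
        """M maintained through random swap sequences equals X^T A X."""
        rng = np.random.default_rng(0)
        A = small_graph.adjacency
        labels = rng.integers(0, 4, small_graph.n_cells).astype(np.int64)
        M = transition_counts(labels, A, 4)
        indptr = A.indptr.astype(np.int64)
        indices = A.indices.astype(np.int64)
        weights = A.data.astype(np.float64)
        for _ in range(200):
            u, v = rng.integers(0, labels.size, 2)
            lu, lv = labels[u], labels[v]
            _sa.relabel(u, lv, labels, indptr, indices, weights, M)
            _sa.relabel(v, lu, labels, indptr, indices, weights, M)
        assert np.abs(M - transition_counts(labels, A, 4)).max() < 1e-10

    def test_annealer_energy_matches_recomputation(self, small_graph):
        """The incumbent energy reported by the annealer equals the
        objective recomputed from scratch on the returned labels."""
        P = np.full((3, 3), 0.1) + np.eye(3) * 0.7
        spec = PatternSpec(np.full(3, 1 / 3), P)
        plate = generate_plate(small_graph.n_cells, "random", seed=0)
        a = assign_celltypes(small_graph, plate, spec, method="gsa", seed=4)
        assert abs(a.objective_value - objective(a.labels, small_graph.adjacency, P)) < 1e-10


class TestAssignCelltypes:
    def test_single_type_degenerate(self, small_graph, small_plate):
        spec = PatternSpec([1.0], [[1.0]])
        a = assign_celltypes(small_graph, small_plate, spec, seed=0)
        assert np.all(a.labels == 0)
        assert a.objective_value == 0.0

    @pytest.mark.parametrize("method", ["gsa", "lsa", "bsa"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_count_constraints_hold_exactly(self, method, seed):
        plate = generate_plate(800, "random", seed=seed)
        graph = build_graph(plate, "knn", 6)
        spec = PatternSpec([0.5, 0.3, 0.2], np.full((3, 3), 0.1) + np.eye(3) * 0.7)
        a = assign_celltypes(graph, plate, spec, method=method, seed=seed)
        assert np.array_equal(a.counts(), target_counts(spec.proportions, 800))

    def test_pure_components_reach_zero_objective(self):
        graph, plate = _clique_pair()
        spec = PatternSpec([0.5, 0.5], np.eye(2))
        hits = sum(
            assign_celltypes(
                graph, plate, spec, method="gsa", schedule=SLOW_SCHEDULE, seed=s
            ).objective_value
            < 1e-9
            for s in range(10)
        )
        assert hits >= 9

    def test_gsa_attains_enumerated_optimum(self):
        """Exhaustive enumeration oracle on a tiny path graph."""
        n = 8
        coords = np.stack([np.arange(n) / n + 1 / (2 * n), np.full(n, 0.5)], axis=1)
        plate = CellPlate(coords, np.array([[0.0, 1.0], [0.0, 1.0]]))
        graph = build_graph(plate, "knn", 1)
        P = np.array([[0.7, 0.3], [0.3, 0.7]])
        spec = PatternSpec([0.5, 0.5], P)
        feasible = set(itertools.permutations([0] * 4 + [1] * 4))
        best = min(objective(np.array(lab), graph.adjacency, P, 2) for lab in feasible)
        hits = sum(
            assign_celltypes(
                graph, plate, spec, method="gsa", schedule=SLOW_SCHEDULE, seed=s
            ).objective_value
            <= best + 1e-9
            for s in range(10)
        )
        assert hits >= 9

    def test_returned_objective_not_worse_than_initial(self):
        plate = generate_plate(600, "random", seed=2)
        graph = build_graph(plate, "knn", 6)
        P = np.full((2, 2), 0.5)
        spec = PatternSpec([0.5, 0.5], P)
        rng = np.random.default_rng(0)
        init = rng.permutation(np.repeat([0, 1], 300))
        e0 = objective(init, graph.adjacency, P)
        a = assign_celltypes(graph, plate, spec, method="gsa", seed=0)
        assert a.objective_value <= e0 + 1e-12

    def test_bsa_recovers_target_and_seed_reproducible(self):
        plate = generate_plate(2000, "random", seed=9)
        graph = build_graph(plate, "knn", 6)
        spec = PatternSpec([0.5, 0.5], [[0.8, 0.2], [0.2, 0.8]])
        a = assign_celltypes(graph, plate, spec, method="bsa", seed=3)
        b = assign_celltypes(graph, plate, spec, method="bsa", seed=3)
        assert np.array_equal(a.labels, b.labels)
        est = estimate_pattern(graph, a.labels)
        assert np.abs(est.transition - spec.transition).max() <= 0.05

    def test_more_types_than_cells_rejected(self, path_graph_4):
        plate, graph = path_graph_4
        spec = PatternSpec(np.full(5, 0.2), np.eye(5))
        with pytest.raises(InvalidArgumentError):
            assign_celltypes(graph, plate, spec)

    def test_disconnected_graph_warns(self):
        graph, plate = _clique_pair(5)
        spec = PatternSpec([0.5, 0.5], np.eye(2))
        with pytest.warns(UserWarning, match="connected components"):
            assign_celltypes(graph, plate, spec, method="gsa", seed=0)
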