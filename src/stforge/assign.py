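"""Cell-type assignment by constrained simulated annealing.

Given a spatial neighborhood graph with adjacency ``A`` and a target
pattern (proportions ``pi``, transition matrix ``P``), find a one-hot
assignment ``X`` minimizing

    || P - C^{-1} X^T A X ||_F,   C = diag(X^T A X 1_K),

subject to each cell having exactly one type (``X 1_K = 1_N``) and exact
per-type counts (``X^T 1_N = round(pi * N)`` via largest-remainder
apportionment).  The problem is combinatorial; three heuristics are
provided:

* **GSA** — global simulated annealing directly over cells, with
  count-preserving label-exchange moves; best for small plates.
* **LSA** — the plate is cut into regular grids and each grid is annealed
  independently against the global target, then concatenated (and
  recalibrated to the exact global counts).
* **BSA** — batched simulated annealing: the plate is partitioned into
  hierarchically shrinking zone windows; zone labels are drawn from
  ``pi`` at the coarsest epoch, inherited by children zones, annealed at
  each epoch on the zone contact graph (a coarse-graining of the
  cell-level energy), expanded to cells, recalibrated to exact counts,
  and refined by a final cell-level pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _sa
from .errors import InvalidArgumentError
from .patterns import PatternSpec, transition_counts
from .plate import CellPlate, NeighborGraph


@dataclass
class AnnealSchedule:
    """Epoch structure and temperature parameters for the annealers.

    The finest zone grid has ``zone_grid = (nx, ny)`` windows per axis
    (about sqrt(N) zones in total); in epoch ``m`` (1-based) of
    ``n_epochs = M`` the window edge lengths are the initial zone
    dimensions scaled by ``2^(M - m)``, and each annealing move bundles
    ``2^m`` label swaps.  Temperature: T0 is auto-calibrated to the mean
    |dE| of 100 probe swaps, cooled geometrically by ``alpha`` until
    ``tmin_frac * T0``, stopping early after ``stall_limit`` consecutive
    rejections.
    """

    n_epochs: int
    zone_grid: tuple[int, int]
    initial_zone_dims: tuple[float, float]
    alpha: float = 0.95
    tmin_frac: float = 1e-4
    stall_limit: int = 200
    moves_per_temp: int | None = None  # default: one proposal per unit
    max_temps: int = 400
    t0_probes: int = 100

    def __post_init__(self):
        if self.n_epochs < 1:
            raise InvalidArgumentError("n_epochs must be >= 1")
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError("alpha must be in (0, 1)")

    def window_dims(self, m: int) -> tuple[float, float]:
        """Window edge lengths in epoch ``m`` (1-based)."""
        f = 2 ** (self.n_epochs - m)
        l0, w0 = self.initial_zone_dims
        return (l0 * f, w0 * f)

    def swaps_per_move(self, m: int) -> int:
        return 2**m

    def describe(self) -> dict:
        return {
            "n_epochs": self.n_epochs,
            "zone_grid": list(self.zone_grid),
            "initial_zone_dims": list(self.initial_zone_dims),
            "window_dims": [list(self.window_dims(m)) for m in range(1, self.n_epochs + 1)],
            "swaps_per_move": [self.swaps_per_move(m) for m in range(1, self.n_epochs + 1)],
            "alpha": self.alpha,
            "tmin_frac": self.tmin_frac,
            "stall_limit": self.stall_limit,
            "max_temps": self.max_temps,
        }


@dataclass
class Assignment:
    """Result of a cell-type assignment run."""

    labels: np.ndarray
    n_types: int
    target_counts: np.ndarray
    objective_value: float
    trace: np.ndarray  # incumbent objective per temperature step
    method: str

    @property
    def onehot(self) -> sp.csr_matrix:
        n = self.labels.size
        return sp.csr_matrix(
            (np.ones(n), (np.arange(n), self.labels)), shape=(n, self.n_types)
        )

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_types)


# --------------------------------------------------------------------------
# objective pieces


def _as_codes(X, n_types: int | None = None) -> tuple[np.ndarray, int]:
    X = np.asarray(X) if not sp.issparse(X) else X
    if sp.issparse(X) or (hasattr(X, "ndim") and X.ndim == 2):
        Xd = X.toarray() if sp.issparse(X) else X
        if np.any((Xd != 0) & (Xd != 1)) or np.any(Xd.sum(axis=1) != 1):
            raise InvalidArgumentError("X must be one-hot (one 1 per row)")
        codes = np.argmax(Xd, axis=1)
        K = Xd.shape[1]
    else:
        codes = np.asarray(X, dtype=int)
        K = int(n_types) if n_types is not None else int(codes.max()) + 1
    return codes, K


def transition_frequency(X, A, n_types: int | None = None) -> np.ndarray:
    """Row-stochastic transition frequency matrix ``C^{-1} X^T A X``.

    ``X`` may be an N x K one-hot matrix or a length-N label vector.
    Rows of ``X^T A X`` that are all zero (types without graph neighbors)
    are returned as all-zero rows with a warning.
    """
    A = sp.csr_matrix(A) if not sp.issparse(A) else A.tocsr()
    codes, K = _as_codes(X, n_types)
    if codes.size != A.shape[0]:
        raise InvalidArgumentError("X and A dimensions do not conform")
    counts = transition_counts(codes, A, K)
    rows = counts.sum(axis=1)
    out = np.zeros((K, K))
    nz = rows > 0
    out[nz] = counts[nz] / rows[nz, None]
    if np.any(~nz):
        warnings.warn(
            f"transition matrix has {int((~nz).sum())} all-zero row(s)", stacklevel=2
        )
    return out


def objective(X, A, P, n_types: int | None = None) -> float:
    """Frobenius norm of ``P - transition_frequency(X, A)``."""
    P = np.asarray(P, dtype=float)
    codes, K = _as_codes(X, n_types if n_types is not None else P.shape[0])
    if P.shape != (K, K):
        raise InvalidArgumentError("P must be K x K matching X")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        T = transition_frequency(codes, A, K)
    return float(np.linalg.norm(P - T, "fro"))


# --------------------------------------------------------------------------
# schedule


def epoch_schedule(
    n: int,
    bounds=None,
    zone_dims: tuple[float, float] | None = None,
    **kwargs,
) -> AnnealSchedule:
    """Default batched-annealing schedule for ``n`` cells.

    The number of epochs is ``M = max(1, floor(log2(n / 1000) / 2) + 1)``
    (clamped to 1 below n=1000, where the formula goes non-positive) and
    the finest zone grid has about ``sqrt(n)`` windows, i.e.
    ``ceil(n**0.25)`` per axis over the first two plate axes.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    M = max(1, int(np.floor(0.5 * np.log2(n / 1000.0))) + 1)
    per_axis = max(1, int(np.ceil(n**0.25)))
    if bounds is None:
        bounds = np.array([[0.0, 1.0], [0.0, 1.0]])
    bounds = np.asarray(bounds, dtype=float)
    if zone_dims is None:
        zone_dims = (
            (bounds[0, 1] - bounds[0, 0]) / per_axis,
            (bounds[1, 1] - bounds[1, 0]) / per_axis,
        )
    return AnnealSchedule(
        n_epochs=M,
        zone_grid=(per_axis, per_axis),
        initial_zone_dims=tuple(zone_dims),
        **kwargs,
    )


# --------------------------------------------------------------------------
# proportions


def target_counts(proportions, n: int) -> np.ndarray:
    """Integer per-type counts from proportions by largest-remainder
    apportionment; ties go to the lowest type index."""
    pi = np.asarray(proportions, dtype=float)
    raw = pi * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    frac = raw - base
    order = np.argsort(-frac, kind="stable")  # stable: ties -> lowest index
    base[order[:short]] += 1
    return base


def recalibrate_proportions(labels, targets, graph=None, seed=None) -> np.ndarray:
    """Switch surplus-type cells to deficient types until counts match
    ``targets`` exactly.  Switched cells are chosen uniformly at random
    among cells of surplus types; cells of already-exact or deficient
    types are never touched.  ``graph`` is accepted for signature
    symmetry with the annealers but not used: the subsequent refinement
    pass, not the recalibration, restores spatial coherence."""
    labels = np.asarray(labels, dtype=int).copy()
    targets = np.asarray(targets, dtype=int)
    if np.any(targets < 0):
        raise InvalidArgumentError("target counts must be non-negative")
    if targets.sum() != labels.size:
        raise InvalidArgumentError("target counts must sum to N")
    K = targets.size
    counts = np.bincount(labels, minlength=K)
    if np.array_equal(counts[:K], targets) and labels.max(initial=-1) < K:
        return labels
    rng = np.random.default_rng(seed)
    surplus_cells = []
    for t in range(K):
        extra = counts[t] - targets[t] if t < counts.size else 0
        if extra > 0:
            cells_t = np.flatnonzero(labels == t)
            surplus_cells.append(rng.choice(cells_t, size=extra, replace=False))
    pool = np.concatenate(surplus_cells) if surplus_cells else np.empty(0, dtype=int)
    rng.shuffle(pool)
    needed = np.repeat(
        np.arange(K), np.maximum(targets - counts[:K], 0)
    )
    labels[pool] = needed
    return labels


# --------------------------------------------------------------------------
# annealing drivers


def _csr_arrays(A: sp.csr_matrix):
    A = A.tocsr().astype(np.float64)
    return (
        A.indptr.astype(np.int64),
        A.indices.astype(np.int64),
        A.data.astype(np.float64),
    )


def _seed_ints(seed, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n, dtype=np.uint64)]


def _run_sa(labels, A, P, swaps, schedule: AnnealSchedule, seed: int):
    """Anneal ``labels`` (modified criteria-free copy) on graph A; returns
    (best_labels, best_energy, trace)."""
    K = P.shape[0]
    labels = np.asarray(labels, dtype=np.int64).copy()
    if K < 2 or np.unique(labels).size < 2:
        e = _sa.energy(transition_counts(labels, A, K), np.asarray(P, float))
        return labels, float(e), np.array([e])
    indptr, indices, weights = _csr_arrays(A)
    M = transition_counts(labels, A, K).astype(np.float64)
    moves = schedule.moves_per_temp or max(50, labels.size)
    best, best_e, n_temps, trace, _acc = _sa.anneal(
        labels,
        indptr,
        indices,
        weights,
        np.ascontiguousarray(M),
        np.ascontiguousarray(np.asarray(P, dtype=np.float64)),
        int(swaps),
        int(moves),
        float(schedule.alpha),
        float(schedule.tmin_frac),
        int(schedule.stall_limit),
        int(schedule.max_temps),
        int(seed),
        int(schedule.t0_probes),
    )
    return best, float(best_e), trace[:n_temps]


def _random_labels_with_counts(counts: np.ndarray, rng) -> np.ndarray:
    labels = np.repeat(np.arange(counts.size), counts)
    rng.shuffle(labels)
    return labels.astype(np.int64)


def assign_celltypes(
    graph: NeighborGraph,
    plate: CellPlate,
    spec: PatternSpec,
    method: str = "bsa",
    schedule: AnnealSchedule | None = None,
    seed: int | None = None,
) -> Assignment:
    """Assign a cell type to every cell of the plate.

    See the module docstring for the three strategies.  The returned
    assignment always satisfies the constraints exactly: one type per
    cell and per-type counts equal to the largest-remainder rounding of
    ``pi * N``.  The objective trace records the incumbent best per
    temperature step (concatenated across epochs for BSA).
    """
    n = graph.n_cells
    if plate.n_cells != n:
        raise InvalidArgumentError("graph and plate must have matching N")
    K = spec.n_types
    if K > n:
        raise InvalidArgumentError("more cell types than cells")
    P = np.asarray(spec.transition, dtype=float)
    targets = target_counts(spec.proportions, n)
    if schedule is None:
        schedule = epoch_schedule(n, bounds=plate.bounds[:2])
    A = graph.adjacency

    n_comp = sp.csgraph.connected_components(A, directed=False, return_labels=False)
    if n_comp > 1:
        warnings.warn(f"neighborhood graph has {n_comp} connected components")

    if K == 1:
        labels = np.zeros(n, dtype=np.int64)
        return Assignment(labels, 1, targets, objective(labels, A, P, 1), np.zeros(1), method)

    seeds = _seed_ints(seed, 4)
    rng = np.random.default_rng(seeds[0])

    if method == "gsa":
        labels0 = _random_labels_with_counts(targets, rng)
        labels, e, trace = _run_sa(labels0, A, P, 1, schedule, seeds[1])
    elif method == "lsa":
        labels, trace = _lsa(graph, plate, P, targets, schedule, seeds, rng)
        e = objective(labels, A, P, K)
    elif method == "bsa":
        labels, trace = _bsa(graph, plate, spec, targets, schedule, seeds, rng)
        e = objective(labels, A, P, K)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")

    assert np.array_equal(np.bincount(labels, minlength=K), targets)
    return Assignment(np.asarray(labels, dtype=int), K, targets, float(e), np.asarray(trace), method)


def _grid_index(plate: CellPlate, nx: int, ny: int) -> np.ndarray:
    """Bin cells into an nx x ny grid over the first two axes."""
    lo = plate.bounds[:2, 0]
    ext = plate.extents[:2]
    gx = np.minimum((plate.coords[:, 0] - lo[0]) / ext[0] * nx, nx - 1).astype(int)
    gy = np.minimum((plate.coords[:, 1] - lo[1]) / ext[1] * ny, ny - 1).astype(int)
    return gx * ny + gy


def _lsa(graph, plate, P, targets, schedule, seeds, rng):
    n = graph.n_cells
    K = P.shape[0]
    pi = targets / targets.sum()
    g = max(1, int(np.ceil(np.sqrt(n / 1000.0))))
    cell_grid = _grid_index(plate, g, g)
    labels = np.zeros(n, dtype=np.int64)
    traces = []
    sub_seeds = _seed_ints(seeds[1], g * g)
    for gi in range(g * g):
        members = np.flatnonzero(cell_grid == gi)
        if members.size == 0:
            continue
        local_targets = target_counts(pi, members.size)
        sub_rng = np.random.default_rng(sub_seeds[gi])
        init = _random_labels_with_counts(local_targets, sub_rng)
        sub = graph.adjacency[members][:, members]
        best, _e, tr = _run_sa(init, sub, P, 1, schedule, sub_seeds[gi])
        labels[members] = best
        traces.append(tr)
    labels = recalibrate_proportions(labels, targets, graph, seeds[2])
    return labels, np.concatenate(traces) if traces else np.zeros(1)


def _bsa(graph, plate, spec, targets, schedule, seeds, rng):
    n = graph.n_cells
    K = spec.n_types
    P = np.asarray(spec.transition, dtype=float)
    A = graph.adjacency
    M_ep = schedule.n_epochs
    nx, ny = schedule.zone_grid

    # finest-grid window index of every cell
    fz_x = np.minimum(
        (plate.coords[:, 0] - plate.bounds[0, 0]) / plate.extents[0] * nx, nx - 1
    ).astype(np.int64)
    fz_y = np.minimum(
        (plate.coords[:, 1] - plate.bounds[1, 0]) / plate.extents[1] * ny, ny - 1
    ).astype(np.int64)

    # label per finest zone; windows at coarser epochs group finest zones,
    # so writing a window's label back to its finest zones implements the
    # child-inherits-parent rule between epochs
    zone_labels = np.full(nx * ny, -1, dtype=np.int64)
    traces = []
    epoch_seeds = _seed_ints(seeds[1], M_ep)
    for m in range(1, M_ep + 1):
        f = 2 ** (M_ep - m)
        wx, wy = (nx + f - 1) // f, (ny + f - 1) // f
        win_of_cell = (fz_x // f) * wy + (fz_y // f)
        occupied, win_compact = np.unique(win_of_cell, return_inverse=True)
        nw = occupied.size
        if m == 1:
            win_labels = rng.choice(K, size=nw, p=spec.proportions)
        else:
            # inherit from the parent epoch through the finest-zone labels
            # (one representative cell per occupied window)
            rep = np.full(nw, -1, dtype=np.int64)
            rep[win_compact[::-1]] = np.arange(n - 1, -1, -1)
            win_labels = zone_labels[fz_x[rep] * ny + fz_y[rep]]
        # zone contact graph: W = B^T A B, diagonal = intra-zone edge mass
        B = sp.csr_matrix(
            (np.ones(n), (np.arange(n), win_compact)), shape=(n, nw)
        )
        W = (B.T @ A @ B).tocsr()
        best, _e, tr = _run_sa(
            win_labels, W, P, schedule.swaps_per_move(m), schedule, epoch_seeds[m - 1]
        )
        traces.append(tr)
        # write back to finest zones (occupied windows only)
        fz_of_cell = fz_x * ny + fz_y
        zone_labels[fz_of_cell] = best[win_compact]

    labels = zone_labels[fz_x * ny + fz_y]
    labels = recalibrate_proportions(labels, targets, graph, seeds[2])
    # final cell-level refinement
    labels, _e, tr = _run_sa(labels, A, P, 1, schedule, seeds[3])
    traces.append(tr)
    return labels, np.concatenate(traces)
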