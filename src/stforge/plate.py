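"""Cell plates and spatial neighborhood graphs.

A *cell plate* is the rectangular (2D) or box-shaped (3D) region on which
cell coordinates are generated, either i.i.d. uniform or on a regular
lattice.  The *neighborhood graph* built on those coordinates is the
substrate of the cell-type assignment optimization: its adjacency matrix A
enters the transition-frequency term X^T A X.

Supported graph constructions: k-nearest neighbors (kNN, union
symmetrized), fixed-radius (strict ``d < r``), Delaunay triangulation, and
shared nearest neighbors (SNN).  Distances may be Euclidean, Manhattan, or
cosine; all constructions return a symmetric binary adjacency with a zero
diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay
from scipy.spatial.distance import cdist

from .errors import DegenerateMetricError, InvalidArgumentError

Metric = Literal["euclidean", "cosine", "manhattan"]
GraphMethod = Literal["knn", "radius", "delaunay", "snn"]

# rows per block when computing pairwise distances chunk-wise; keeps the
# working set ~ _BLOCK * N doubles regardless of N
_BLOCK = 512


@dataclass
class CellPlate:
    """Coordinates of N cells inside axis-aligned bounds.

    Attributes
    ----------
    coords : ndarray, shape (N, d)
        Cell positions, d in {2, 3}, arbitrary length units.
    bounds : ndarray, shape (d, 2)
        Per-axis (min, max) intervals containing every coordinate.
    """

    coords: np.ndarray
    bounds: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise InvalidArgumentError("coords must be N x d with d in {2, 3}")
        if self.bounds.shape != (self.coords.shape[1], 2):
            raise InvalidArgumentError("bounds must be d x 2 (min, max)")
        if np.any(self.bounds[:, 1] <= self.bounds[:, 0]):
            raise InvalidArgumentError("bounds must be non-degenerate intervals")
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        if np.any(self.coords < lo) or np.any(self.coords > hi):
            raise InvalidArgumentError("coordinates fall outside bounds")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def extents(self) -> np.ndarray:
        """Per-axis lengths of the bounding box."""
        return self.bounds[:, 1] - self.bounds[:, 0]


@dataclass
class NeighborGraph:
    """Symmetric binary spatial adjacency over the cells of a plate.

    ``adjacency`` is an N x N scipy CSR matrix with entries in {0, 1},
    zero diagonal and ``A == A.T``.
    """

    adjacency: sp.csr_matrix
    method: GraphMethod
    param: float
    metric: Metric = "euclidean"

    def __post_init__(self):
        a = sp.csr_matrix(self.adjacency)
        a.eliminate_zeros()
        self.adjacency = a

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return self.adjacency.nnz // 2

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)


def generate_plate(
    n: int,
    mode: Literal["random", "grid"] = "random",
    bounds=None,
    dim: int = 2,
    seed: int | None = None,
) -> CellPlate:
    """Generate ``n`` cell coordinates on a plate.

    Parameters
    ----------
    n : int
        Number of cells (>= 1).
    mode : {"random", "grid"}
        ``random`` draws i.i.d. uniform coordinates per axis; ``grid``
        places cells at the centers of the most-square lattice with at
        least ``n`` sites and returns exactly ``n`` (row-major truncation).
    bounds : array-like, shape (d, 2), optional
        Per-axis (min, max); defaults to the unit square/cube.
    dim : {2, 3}
    seed : int, optional
        Seed for the random mode; the same seed reproduces coordinates
        bitwise.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if dim not in (2, 3):
        raise InvalidArgumentError("dim must be 2 or 3")
    if bounds is None:
        bounds = np.array([[0.0, 1.0]] * dim)
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (dim, 2) or np.any(bounds[:, 1] <= bounds[:, 0]):
        raise InvalidArgumentError("bounds must be d x 2 with min < max")

    if mode == "random":
        rng = np.random.default_rng(seed)
        coords = rng.uniform(bounds[:, 0], bounds[:, 1], size=(n, dim))
    elif mode == "grid":
        coords = _grid_coords(n, bounds, dim)
    else:
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    return CellPlate(coords=coords, bounds=bounds)


def _grid_coords(n: int, bounds: np.ndarray, dim: int) -> np.ndarray:
    # most-square lattice with >= n sites: round each axis count up from
    # the d-th root, shaving axes while the product still covers n
    base = int(np.ceil(n ** (1.0 / dim)))
    shape = [base] * dim
    for ax in range(dim):
        while shape[ax] > 1 and int(np.prod(shape)) // shape[ax] * (shape[ax] - 1) >= n:
            shape[ax] -= 1
    axes = [
        bounds[ax, 0] + (np.arange(shape[ax]) + 0.5) / shape[ax] * (bounds[ax, 1] - bounds[ax, 0])
        for ax in range(dim)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=1)  # row-major order
    return coords[:n]


def _pairwise_block(coords: np.ndarray, rows: slice, metric: Metric) -> np.ndarray:
    if metric == "euclidean":
        return cdist(coords[rows], coords, metric="euclidean")
    if metric == "manhattan":
        return cdist(coords[rows], coords, metric="cityblock")
    if metric == "cosine":
        return cdist(coords[rows], coords, metric="cosine")
    raise InvalidArgumentError(f"unknown metric {metric!r}")


def _check_cosine_degenerate(coords: np.ndarray) -> None:
    norms = np.linalg.norm(coords, axis=1)
    if np.any(norms == 0):
        raise DegenerateMetricError("cosine metric undefined for points at the origin")
    unit = coords / norms[:, None]
    if np.allclose(unit, unit[0], atol=1e-12):
        raise DegenerateMetricError(
            "cosine metric degenerate: all points share one direction"
        )


def build_graph(
    plate: CellPlate,
    method: GraphMethod = "knn",
    param: float = 6,
    metric: Metric = "euclidean",
    snn_shared: int = 1,
) -> NeighborGraph:
    """Build the spatial neighborhood graph of a plate.

    Parameters
    ----------
    plate : CellPlate
    method : {"knn", "radius", "delaunay", "snn"}
        kNN nominates each cell's ``k`` nearest neighbors and symmetrizes
        by union (an edge exists if either endpoint nominates the other);
        ties at the k-th distance are broken by lowest index.  ``radius``
        connects pairs with strict ``d(i, j) < r``.  ``delaunay`` uses the
        edges of the Delaunay triangulation (Euclidean geometry).  ``snn``
        connects kNN candidates sharing at least ``snn_shared`` common
        kNN neighbors.
    param : float
        ``k`` for knn/snn (1 <= k < N) or ``r`` for radius (> 0); ignored
        for delaunay.
    metric : {"euclidean", "cosine", "manhattan"}
        Distance used for knn/radius/snn.
    """
    coords = plate.coords
    n = plate.n_cells
    if metric == "cosine":
        _check_cosine_degenerate(coords)

    if method == "knn":
        adj = _sym_union(_knn_directed(coords, int(param), metric))
    elif method == "radius":
        r = float(param)
        if r <= 0:
            raise InvalidArgumentError("radius must be > 0")
        adj = _radius_graph(coords, r, metric)
    elif method == "delaunay":
        adj = _delaunay_graph(coords)
    elif method == "snn":
        directed = _knn_directed(coords, int(param), metric).astype(np.int32)
        union = _sym_union(directed)
        shared = directed @ directed.T  # counts of common kNN neighbors
        shared.setdiag(0)
        mask = shared >= snn_shared
        adj = union.multiply(mask)
        adj.eliminate_zeros()
        adj = (adj > 0).astype(np.int8).tocsr()
    else:
        raise InvalidArgumentError(f"unknown graph method {method!r}")

    adj.setdiag(0)
    adj.eliminate_zeros()
    return NeighborGraph(adjacency=adj.tocsr(), method=method, param=float(param), metric=metric)


def _knn_directed(coords: np.ndarray, k: int, metric: Metric) -> sp.csr_matrix:
    n = coords.shape[0]
    if not 1 <= k < n:
        raise InvalidArgumentError(f"k must satisfy 1 <= k < N, got k={k}, N={n}")
    rows = np.repeat(np.arange(n), k)
    cols = np.empty(n * k, dtype=np.int64)
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        d = _pairwise_block(coords, slice(start, stop), metric)
        idx = np.arange(n)[None, :].repeat(stop - start, axis=0)
        d[np.arange(stop - start), np.arange(start, stop)] = np.inf  # no self
        # stable ordering (distance, index) makes ties deterministic
        order = np.lexsort((idx, d), axis=1)[:, :k]
        cols[start * k : stop * k] = order.ravel()
    data = np.ones(n * k, dtype=np.int8)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def _sym_union(directed: sp.csr_matrix) -> sp.csr_matrix:
    sym = directed.maximum(directed.T)
    return sym.astype(np.int8).tocsr()


def _radius_graph(coords: np.ndarray, r: float, metric: Metric) -> sp.csr_matrix:
    n = coords.shape[0]
    rows_all, cols_all = [], []
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        d = _pairwise_block(coords, slice(start, stop), metric)
        rr, cc = np.nonzero(d < r)
        keep = (rr + start) != cc
        rows_all.append(rr[keep] + start)
        cols_all.append(cc[keep])
    rows = np.concatenate(rows_all) if rows_all else np.empty(0, dtype=int)
    cols = np.concatenate(cols_all) if cols_all else np.empty(0, dtype=int)
    adj = sp.csr_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return adj.maximum(adj.T).tocsr()


def _delaunay_graph(coords: np.ndarray) -> sp.csr_matrix:
    n = coords.shape[0]
    if n < coords.shape[1] + 2:
        raise InvalidArgumentError("too few points for a Delaunay triangulation")
    tri = Delaunay(coords)
    pairs = set()
    for simplex in tri.simplices:
        for i in range(len(simplex)):
            for j in range(i + 1, len(simplex)):
                a, b = int(simplex[i]), int(simplex[j])
                pairs.add((a, b))
                pairs.add((b, a))
    rows, cols = zip(*pairs)
    adj = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return adj


def write_coords_tsv(plate: CellPlate, path) -> None:
    """Write coordinates as TSV ``cell_id<TAB>x<TAB>y[<TAB>z]``."""
    import pandas as pd

    cols = ["x", "y", "z"][: plate.dim]
    df = pd.DataFrame(plate.coords, columns=cols)
    df.insert(0, "cell_id", np.arange(plate.n_cells))
    df.to_csv(path, sep="\t", index=False)


def read_coords_tsv(path, bounds=None) -> CellPlate:
    """Read a coordinate TSV written by :func:`write_coords_tsv`.

    Bounds default to the coordinate-wise min/max (expanded minimally if a
    coordinate axis is degenerate).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    axes = [c for c in ("x", "y", "z") if c in df.columns]
    coords = df[axes].to_numpy(dtype=float)
    if bounds is None:
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        span = np.where(hi - lo <= 0, 1.0, 0.0)
        bounds = np.stack([lo - span, hi + span], axis=1)
    return CellPlate(coords=coords, bounds=np.asarray(bounds, dtype=float))


def write_adjacency_mtx(graph: NeighborGraph, path) -> None:
    """Export the adjacency as Matrix Market coordinate (pattern symmetric)."""
    from scipy.io import mmwrite

    mmwrite(str(path), sp.triu(graph.adjacency), symmetry="symmetric", field="pattern")
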