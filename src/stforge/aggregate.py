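"""Spot-level aggregation of single-cell spatial data.

Sequencing-based platforms measure expression per capture *spot* rather
than per cell.  This module lays a regular lattice of circular or
rectangular spots over the plate, sums the counts of the cells each spot
captures, and records the exact per-spot cell-type composition — the
ground truth that deconvolution benchmarks need.

Membership conventions: rectangles use half-open intervals
``[min, max)`` per axis so abutting spots never double-count a cell on a
shared edge; circles use the strict interior (``d < radius``).  Cells in
lattice gaps (circle lattices leave gaps) are counted as uncaptured.
Aggregation uses the first two coordinate axes; 3D plates are projected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .errors import InvalidArgumentError
from .expression import SingleCellST


@dataclass
class SpotGrid:
    """Regular lattice of capture spots."""

    centers: np.ndarray  # n_spots x 2
    spot_shape: str  # "circle" | "rectangle"
    spot_size: tuple[float, float]  # (radius, radius) or (side_x, side_y)
    lattice: str  # "square" | "hexagonal"
    bounds: np.ndarray

    @property
    def n_spots(self) -> int:
        return self.centers.shape[0]


@dataclass
class SpotST:
    """Spot-level dataset with ground-truth compositions."""

    grid: SpotGrid
    spot_counts: sp.csr_matrix  # spots x genes
    composition: np.ndarray  # spots x K integer cell counts
    gene_ids: list[str]
    type_names: list[str]
    uncaptured: int

    @property
    def n_cells(self) -> np.ndarray:
        """Cells captured per spot."""
        return self.composition.sum(axis=1)

    @property
    def proportions(self) -> np.ndarray:
        """Row-normalized composition; empty spots give zero rows."""
        tot = self.composition.sum(axis=1, keepdims=True).astype(float)
        out = np.zeros_like(self.composition, dtype=float)
        nz = tot[:, 0] > 0
        out[nz] = self.composition[nz] / tot[nz]
        return out


def make_spot_lattice(
    bounds,
    shape: str = "circle",
    size: float | tuple[float, float] = 0.05,
    lattice: str = "square",
) -> SpotGrid:
    """Lay a regular spot lattice inside ``bounds`` (first two axes).

    ``size`` is the radius for circles, or the side length(s) for
    rectangles.  Square lattices use a pitch equal to the spot diameter /
    side so spots abut without overlapping; hexagonal lattices offset
    alternate rows by half a pitch with row spacing ``pitch * sqrt(3)/2``.
    Only spots lying fully inside the bounds are kept.
    """
    bounds = np.asarray(bounds, dtype=float)[:2]
    ext = bounds[:, 1] - bounds[:, 0]
    if shape not in ("circle", "rectangle"):
        raise InvalidArgumentError(f"unknown spot shape {shape!r}")
    if lattice not in ("square", "hexagonal"):
        raise InvalidArgumentError(f"unknown lattice {lattice!r}")

    if shape == "circle":
        r = float(size if np.isscalar(size) else size[0])
        if r <= 0:
            raise InvalidArgumentError("radius must be > 0")
        half = np.array([r, r])
    else:
        sx, sy = (float(size), float(size)) if np.isscalar(size) else map(float, size)
        if sx <= 0 or sy <= 0:
            raise InvalidArgumentError("side lengths must be > 0")
        half = np.array([sx / 2.0, sy / 2.0])
    if np.any(2 * half > ext):
        raise InvalidArgumentError("spot does not fit inside the plate bounds")

    pitch = 2 * half  # abutting, non-overlapping
    if lattice == "square":
        nx = int(np.floor(ext[0] / pitch[0]))
        ny = int(np.floor(ext[1] / pitch[1]))
        xs = bounds[0, 0] + (np.arange(nx) + 0.5) * pitch[0]
        ys = bounds[1, 0] + (np.arange(ny) + 0.5) * pitch[1]
        cx, cy = np.meshgrid(xs, ys, indexing="ij")
        centers = np.stack([cx.ravel(), cy.ravel()], axis=1)
    else:
        row_step = pitch[1] * np.sqrt(3.0) / 2.0
        centers_list = []
        y = bounds[1, 0] + half[1]
        row = 0
        while y + half[1] <= bounds[1, 1] + 1e-12:
            off = (pitch[0] / 2.0) if row % 2 else 0.0
            x = bounds[0, 0] + half[0] + off
            while x + half[0] <= bounds[0, 1] + 1e-12:
                centers_list.append((x, y))
                x += pitch[0]
            y += row_step
            row += 1
        centers = np.asarray(centers_list, dtype=float).reshape(-1, 2)

    return SpotGrid(
        centers=centers,
        spot_shape=shape,
        spot_size=(half[0], half[1]) if shape == "rectangle" else (half[0], half[0]),
        lattice=lattice,
        bounds=bounds,
    )


def aggregate_to_spots(sc: SingleCellST, grid: SpotGrid) -> SpotST:
    """Aggregate a single-cell dataset onto a spot lattice.

    A cell is captured by a spot iff its center lies inside the spot's
    shape; each cell belongs to at most one spot (lattices are
    non-overlapping).  Captured cells' count rows are summed per spot;
    compositions tally types; cells in no spot are counted as uncaptured.
    Empty spots are retained with zero rows.
    """
    coords = sc.plate.coords[:, :2]
    n = coords.shape[0]
    spot_of_cell = _assign_spots(coords, grid)

    names = sorted(np.unique(sc.labels).tolist())
    lookup = {t: i for i, t in enumerate(names)}
    codes = np.asarray([lookup[t] for t in sc.labels])

    captured = spot_of_cell >= 0
    S = sp.csr_matrix(
        (
            np.ones(int(captured.sum())),
            (spot_of_cell[captured], np.flatnonzero(captured)),
        ),
        shape=(grid.n_spots, n),
    )
    spot_counts = (S @ sc.counts).tocsr()
    composition = np.zeros((grid.n_spots, len(names)), dtype=int)
    np.add.at(composition, (spot_of_cell[captured], codes[captured]), 1)

    return SpotST(
        grid=grid,
        spot_counts=spot_counts,
        composition=composition,
        gene_ids=list(sc.gene_ids),
        type_names=[str(t) for t in names],
        uncaptured=int(n - captured.sum()),
    )


def _assign_spots(coords: np.ndarray, grid: SpotGrid) -> np.ndarray:
    """Spot index per cell, -1 when uncaptured."""
    from scipy.spatial import cKDTree

    n = coords.shape[0]
    out = np.full(n, -1, dtype=np.int64)
    if grid.n_spots == 0:
        return out
    hx, hy = grid.spot_size
    tree = cKDTree(grid.centers)
    # a few nearest candidates suffice: lattices are non-overlapping, and
    # half-open rectangle membership picks exactly one of abutting spots
    kq = min(4, grid.n_spots)
    _d, cand = tree.query(coords, k=kq)
    cand = np.atleast_2d(cand.reshape(n, -1))
    for j in range(cand.shape[1]):
        c = grid.centers[cand[:, j]]
        dx = coords[:, 0] - c[:, 0]
        dy = coords[:, 1] - c[:, 1]
        if grid.spot_shape == "circle":
            inside = dx * dx + dy * dy < hx * hx
        else:
            inside = (-hx <= dx) & (dx < hx) & (-hy <= dy) & (dy < hy)
        take = inside & (out < 0)
        out[take] = cand[take, j]
    return out
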