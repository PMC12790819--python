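"""Gene expression attachment for simulated cells.

After cell-type assignment, each simulated cell needs an expression
profile.  Two routes are provided: sampling (with replacement) from a
labeled single-cell reference of the matching type, or a built-in
parametric count simulator drawing negative-binomial counts with
type-specific marker blocks.  A self-contained synthetic fixture emulates
a layered mouse visual cortex dataset (six types, three excitatory layers)
for tests and examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import InvalidArgumentError, MissingTypeError
from .plate import CellPlate


@dataclass
class ExpressionReference:
    """Labeled cells x genes count matrix used as a sampling pool."""

    counts: sp.csr_matrix
    cell_labels: np.ndarray
    gene_ids: list[str]

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.cell_labels = np.asarray(self.cell_labels)
        if self.counts.shape[0] != self.cell_labels.size:
            raise InvalidArgumentError("counts rows must match cell_labels length")
        if self.counts.shape[1] != len(self.gene_ids):
            raise InvalidArgumentError("counts columns must match gene_ids length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidArgumentError("gene_ids must be unique")
        if self.counts.nnz and (
            np.any(self.counts.data < 0) or np.any(self.counts.data % 1 != 0)
        ):
            raise InvalidArgumentError("counts must be non-negative integers")
        self.type_index = {
            t: np.flatnonzero(self.cell_labels == t)
            for t in np.unique(self.cell_labels)
        }

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def types(self) -> list:
        return list(self.type_index)


@dataclass
class SingleCellST:
    """Single-cell-resolution simulated spatial dataset."""

    plate: CellPlate
    labels: np.ndarray
    counts: sp.csr_matrix
    gene_ids: list[str]
    provenance: np.ndarray | None = None  # reference cell row per simulated cell

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.counts = sp.csr_matrix(self.counts)
        n = self.plate.n_cells
        if not (self.labels.size == n == self.counts.shape[0]):
            raise InvalidArgumentError("plate, labels, and counts disagree on N")
        if self.provenance is not None and np.asarray(self.provenance).size != n:
            raise InvalidArgumentError("provenance must have one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.plate.n_cells

    def as_reference(self) -> ExpressionReference:
        """View this dataset as a sampling reference."""
        return ExpressionReference(
            counts=self.counts, cell_labels=self.labels, gene_ids=list(self.gene_ids)
        )


def sample_expression(
    labels, ref: ExpressionReference, seed: int | None = None
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Draw an expression profile for every cell from same-type reference
    cells, uniformly with replacement.

    Returns (counts, provenance) where ``provenance[i]`` is the reference
    row copied into simulated cell ``i``.
    """
    labels = np.asarray(labels)
    missing = set(np.unique(labels)) - set(ref.type_index)
    if missing:
        raise MissingTypeError(missing)
    rng = np.random.default_rng(seed)
    provenance = np.empty(labels.size, dtype=np.int64)
    for t, rows in ref.type_index.items():
        mask = labels == t
        provenance[mask] = rng.choice(rows, size=int(mask.sum()), replace=True)
    counts = ref.counts[provenance]
    return counts.tocsr(), provenance


def simulate_reference(
    n_types: int,
    n_genes: int = 200,
    n_cells_per_type: int = 100,
    baseline_mean: float = 2.0,
    dispersion: float = 2.0,
    marker_blocks: dict[int, tuple[np.ndarray, float]] | None = None,
    n_markers_per_type: int = 20,
    marker_fold: float = 8.0,
    zero_inflation: float = 0.0,
    type_names: list[str] | None = None,
    seed: int | None = None,
) -> ExpressionReference:
    """Simulate a labeled single-cell reference with NB counts.

    Counts for gene g in a type-t cell are negative binomial with mean
    ``mu = baseline_mean * fold(t, g)`` and variance ``mu + mu^2 /
    dispersion`` (gamma-Poisson mixture).  Marker structure defaults to
    ``n_markers_per_type`` disjoint genes per type upregulated by
    ``marker_fold``; pass ``marker_blocks`` as ``{type: (gene_indices,
    fold)}`` to override.  ``zero_inflation`` optionally zeroes each count
    independently with that probability.
    """
    if n_types < 1 or n_genes < 1 or n_cells_per_type < 1:
        raise InvalidArgumentError("n_types, n_genes, n_cells_per_type must be >= 1")
    if baseline_mean <= 0 or dispersion <= 0:
        raise InvalidArgumentError("baseline_mean and dispersion must be > 0")
    if not 0 <= zero_inflation < 1:
        raise InvalidArgumentError("zero_inflation must be in [0, 1)")

    if marker_blocks is None:
        marker_blocks = {}
        for t in range(n_types):
            lo = t * n_markers_per_type
            hi = min(lo + n_markers_per_type, n_genes)
            marker_blocks[t] = (np.arange(lo, hi), marker_fold)

    rng = np.random.default_rng(seed)
    means = np.full((n_types, n_genes), float(baseline_mean))
    for t, (genes, fold) in marker_blocks.items():
        means[t, np.asarray(genes, dtype=int)] *= float(fold)

    n_cells = n_types * n_cells_per_type
    labels = np.repeat(np.arange(n_types), n_cells_per_type)
    mu = means[labels]  # cells x genes
    lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    counts = rng.poisson(lam)
    if zero_inflation > 0:
        counts[rng.random(counts.shape) < zero_inflation] = 0

    names = type_names or [f"type{t}" for t in range(n_types)]
    gene_ids = [f"gene{g}" for g in range(n_genes)]
    return ExpressionReference(
        counts=sp.csr_matrix(counts),
        cell_labels=np.asarray([names[t] for t in labels]),
        gene_ids=gene_ids,
    )


# Composition of the layered-cortex fixture: six cell types, the three
# excitatory populations confined to distinct strata, the rest dispersed.
STARMAP_LIKE_COUNTS = {
    "Astro": 141,
    "Endo": 150,
    "eL2/3": 258,
    "eL4": 198,
    "eL6": 287,
    "Oligo": 200,
}
_LAYERED_TYPES = ("eL2/3", "eL4", "eL6")


def starmap_like_fixture(seed: int | None = 0, n_genes: int = 200) -> SingleCellST:
    """Synthetic layered-cortex dataset (1234 cells, six types).

    Emulates the composition and laminar organization of a STARmap-style
    mouse visual cortex slice: 141 astrocytes, 150 endothelial cells,
    258 eL2/3, 198 eL4, and 287 eL6 excitatory neurons, and 200
    oligodendrocytes on the unit square.  The excitatory types occupy
    three y-strata (so each one's self-transition dominates its
    cross-transitions); astrocytes, endothelial cells, and
    oligodendrocytes are dispersed uniformly.  Expression is drawn from
    the built-in negative-binomial simulator with 20 marker genes per
    type at fold-change 8 over baseline mean 2 (package defaults).  The
    data are fully synthetic; no external files are touched.
    """
    names = list(STARMAP_LIKE_COUNTS)
    counts_per_type = np.array([STARMAP_LIKE_COUNTS[t] for t in names])
    n = int(counts_per_type.sum())
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed).generate_state(2, dtype=np.uint64)

    coords = rng.uniform(size=(n, 2))
    plate = CellPlate(coords=coords, bounds=np.array([[0.0, 1.0], [0.0, 1.0]]))

    dispersed = [t for t in names if t not in _LAYERED_TYPES]
    n_dispersed = sum(STARMAP_LIKE_COUNTS[t] for t in dispersed)
    labels = np.empty(n, dtype=object)
    picked = rng.choice(n, size=n_dispersed, replace=False)
    pool = np.repeat(dispersed, [STARMAP_LIKE_COUNTS[t] for t in dispersed])
    rng.shuffle(pool)
    labels[picked] = pool

    rest = np.setdiff1d(np.arange(n), picked)
    rest = rest[np.argsort(coords[rest, 1], kind="stable")]  # bottom-up strata
    start = 0
    for t in _LAYERED_TYPES:
        c = STARMAP_LIKE_COUNTS[t]
        labels[rest[start : start + c]] = t
        start += c
    labels = labels.astype(str)

    # one NB profile per fixture cell, same marker design as
    # simulate_reference defaults (20 markers/type, fold 8, baseline 2)
    rng2 = np.random.default_rng(int(ss[1] % (2**31)))
    means = np.full((len(names), n_genes), 2.0)
    for t in range(len(names)):
        lo = t * 20
        means[t, lo : min(lo + 20, n_genes)] *= 8.0
    idx = np.asarray([names.index(t) for t in labels])
    mu = means[idx]
    lam = rng2.gamma(shape=2.0, scale=mu / 2.0)
    counts = sp.csr_matrix(rng2.poisson(lam))

    return SingleCellST(
        plate=plate,
        labels=labels,
        counts=counts,
        gene_ids=[f"gene{g}" for g in range(n_genes)],
        provenance=None,
    )
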