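"""Evaluation metrics for simulated spatial transcriptomics data.

Four families:

* clustering agreement between two label partitions — adjusted Rand index
  (ARI) and normalized mutual information (NMI, arithmetic-mean
  normalizer, natural log);
* spatial-pattern matrices of a labeled graph — the transition matrix
  (TM), a K x 3 centrality score matrix (CSM: group degree centrality,
  mean member clustering coefficient, normalized group closeness), and a
  permutation-null neighborhood enrichment z-score matrix (NEM); two
  datasets are compared by the Frobenius norm of the matrix difference;
* point-pattern statistics — Ripley's K/L per cell type against the
  complete-spatial-randomness baseline ``L(t) = t``, with cosine
  similarity between L-curves as a scalar summary;
* ligand-receptor set agreement — the overlap similarity index SI
  (intersection over the smaller set) and the rank-based RSI.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist

from .errors import InvalidArgumentError
from .patterns import estimate_pattern, transition_counts
from .plate import NeighborGraph

# --------------------------------------------------------------------------
# clustering agreement


@dataclass
class ContingencyTable:
    """Cluster overlap counts n_ij between two partitions."""

    counts: np.ndarray

    @classmethod
    def from_labels(cls, labels_a, labels_b) -> "ContingencyTable":
        a = np.asarray(labels_a)
        b = np.asarray(labels_b)
        if a.size != b.size:
            raise InvalidArgumentError("label vectors must have equal length")
        if a.size == 0:
            raise InvalidArgumentError("label vectors must be non-empty")
        _, ai = np.unique(a, return_inverse=True)
        _, bi = np.unique(b, return_inverse=True)
        counts = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
        np.add.at(counts, (ai, bi), 1)
        return cls(counts=counts)

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index of two partitions (1 for identical ones)."""
    t = ContingencyTable.from_labels(labels_a, labels_b)
    sum_ij = _comb2(t.counts.astype(float)).sum()
    sum_i = _comb2(t.row_marginals.astype(float)).sum()
    sum_j = _comb2(t.col_marginals.astype(float)).sum()
    n2 = _comb2(float(t.total))
    expected = sum_i * sum_j / n2 if n2 > 0 else 0.0
    max_index = 0.5 * (sum_i + sum_j)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information, I(A;B) / ((H(A) + H(B)) / 2).

    Base-invariant (computed in natural log).  Two identical one-cluster
    partitions are defined to agree perfectly (1.0).
    """
    t = ContingencyTable.from_labels(labels_a, labels_b)
    n = t.total
    pij = t.counts / n
    pi = t.row_marginals / n
    pj = t.col_marginals / n
    nzi = pi > 0
    nzj = pj > 0
    h_a = -np.sum(pi[nzi] * np.log(pi[nzi]))
    h_b = -np.sum(pj[nzj] * np.log(pj[nzj]))
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    nz = pij > 0
    mi = np.sum(pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz]))
    return float(mi / ((h_a + h_b) / 2.0))


# --------------------------------------------------------------------------
# spatial pattern matrices


def _spec_or_matrix(x) -> np.ndarray:
    from .patterns import PatternSpec

    if isinstance(x, PatternSpec):
        return np.asarray(x.transition, dtype=float)
    if isinstance(x, tuple) and len(x) == 2:
        graph, labels = x
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(estimate_pattern(graph, labels).transition)
    return np.asarray(x, dtype=float)


def transition_discrepancy(a, b) -> float:
    """Frobenius distance between two transition matrices.

    Each argument may be a PatternSpec, a (graph, labels) tuple, or a
    K x K matrix; type sets must be aligned (same K, same order).
    """
    ta = _spec_or_matrix(a)
    tb = _spec_or_matrix(b)
    if ta.shape != tb.shape:
        raise InvalidArgumentError("transition matrices must have matching shape")
    return float(np.linalg.norm(ta - tb, "fro"))


def _clustering_coefficients(A: sp.csr_matrix) -> np.ndarray:
    """Local clustering coefficient per node of a simple undirected graph."""
    A = A.tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    tri = np.asarray((A @ A).multiply(A).sum(axis=1)).ravel() / 2.0
    denom = deg * (deg - 1) / 2.0
    out = np.zeros(A.shape[0])
    nz = denom > 0
    out[nz] = tri[nz] / denom[nz]
    return out


def csm(graph: NeighborGraph, labels) -> np.ndarray:
    """Centrality score matrix, K x 3 columns [G1, G2, G3].

    For each type's member set: G1 is the fraction of non-members
    adjacent to at least one member (group degree centrality); G2 is the
    mean local clustering coefficient over member nodes; G3 is the group
    closeness, the number of reachable non-members divided by the sum of
    their shortest-path distances to the group (unreachable nodes are
    excluded with a warning).  A type owning every cell leaves G1 and G3
    as NaN.
    """
    labels = np.asarray(labels)
    if labels.size != graph.n_cells:
        raise InvalidArgumentError("labels must cover the graph")
    A = graph.adjacency
    names = np.unique(labels)
    cc = _clustering_coefficients(A)
    out = np.full((names.size, 3), np.nan)
    for k, t in enumerate(names):
        members = np.flatnonzero(labels == t)
        non = np.flatnonzero(labels != t)
        out[k, 1] = cc[members].mean()
        if non.size == 0:
            warnings.warn(f"type {t!r} owns all cells; G1/G3 undefined")
            continue
        touched = np.asarray(A[members].sum(axis=0)).ravel()[non] > 0
        out[k, 0] = touched.sum() / non.size
        dist = dijkstra(A, directed=False, unweighted=True, indices=members, min_only=True)
        d = dist[non]
        finite = np.isfinite(d)
        if not np.all(finite):
            warnings.warn(
                f"{int((~finite).sum())} nodes unreachable from type {t!r}; excluded from G3"
            )
        if finite.any() and d[finite].sum() > 0:
            out[k, 2] = finite.sum() / d[finite].sum()
        else:
            out[k, 2] = np.nan
    return out


def _multiset_permutations(codes: np.ndarray):
    """Distinct permutations of a small label multiset."""
    seen = set()
    for perm in itertools.permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)


def nem(
    graph: NeighborGraph,
    labels,
    n_perms: int = 1000,
    seed: int | None = None,
    method: str = "shuffle",
) -> np.ndarray:
    """Neighborhood enrichment z-score matrix (K x K).

    Counts inter-type edge endpoints ``x = X^T A X`` on the fixed graph,
    builds a null by shuffling the label vector ``n_perms`` times
    (``method="shuffle"``) or by enumerating every distinct permutation
    of the label multiset (``method="exhaustive"``, tiny N only), and
    returns ``z = (x - mu) / sigma`` with population-sd normalization.
    Pairs with ``sigma = 0`` and ``x = mu`` get z = 0.
    """
    labels = np.asarray(labels)
    if labels.size != graph.n_cells:
        raise InvalidArgumentError("labels must cover the graph")
    if method == "shuffle" and n_perms < 2:
        raise InvalidArgumentError("n_perms must be >= 2")
    names, codes = np.unique(labels, return_inverse=True)
    K = names.size
    A = graph.adjacency
    x = transition_counts(codes, A, K)

    if method == "exhaustive":
        perms = list(_multiset_permutations(codes))
        samples = np.stack([transition_counts(p, A, K) for p in perms])
    elif method == "shuffle":
        rng = np.random.default_rng(seed)
        samples = np.empty((n_perms, K, K))
        shuffled = codes.copy()
        for i in range(n_perms):
            rng.shuffle(shuffled)
            samples[i] = transition_counts(shuffled, A, K)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")

    mu = samples.mean(axis=0)
    sigma = samples.std(axis=0)  # population sd over the null draws
    z = np.zeros((K, K))
    nz = sigma > 0
    z[nz] = (x - mu)[nz] / sigma[nz]
    # sigma == 0 and x != mu cannot happen for shuffle nulls that include
    # the observed configuration; guard with +/- inf for completeness
    deg = (sigma == 0) & (x != mu)
    z[deg] = np.sign((x - mu)[deg]) * np.inf
    return z


def same_type_edge_fraction(graph: NeighborGraph, labels) -> float:
    """Join-count statistic: fraction of edges joining same-type cells.

    Increases monotonically as a two-type field moves from interspersed
    (mixed) through enclosing (compartmentalized) to stratified (layered)
    organization.
    """
    labels = np.asarray(labels)
    names, codes = np.unique(labels, return_inverse=True)
    counts = transition_counts(codes, graph.adjacency, names.size)
    tot = counts.sum()
    if tot == 0:
        raise InvalidArgumentError("graph has no edges")
    return float(np.trace(counts) / tot)


# --------------------------------------------------------------------------
# Ripley point-pattern statistics


@dataclass
class CurveSet:
    """Per-type Ripley's L curves on a common distance grid."""

    distances: np.ndarray
    curves: dict[str, np.ndarray]

    def __post_init__(self):
        t = np.asarray(self.distances, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0) or np.any(t <= 0):
            raise InvalidArgumentError("distances must be positive strictly increasing")
        self.distances = t
        for k, v in self.curves.items():
            if np.asarray(v).size != t.size:
                raise InvalidArgumentError(f"curve {k!r} length mismatch")

    @property
    def csr_baseline(self) -> np.ndarray:
        """Expected L under complete spatial randomness: L(t) = t."""
        return self.distances.copy()


def ripley_l(
    coords: np.ndarray,
    bounds,
    t_grid: np.ndarray,
    correction: str = "none",
) -> np.ndarray:
    """Ripley's L function of one point set.

    ``K_hat(t) = |A| / (n (n - 1)) * sum_{i != j} 1[d_ij <= t]`` and
    ``L(t) = sqrt(K_hat(t) / pi)``.  With ``correction="border"`` only
    points farther than ``t`` from the plate boundary contribute as
    centers (reduced-sample estimator); the default applies no edge
    correction, which is adequate when curves are compared on matched
    geometry.
    """
    coords = np.asarray(coords, dtype=float)[:, :2]
    n = coords.shape[0]
    if n < 2:
        raise InvalidArgumentError("need at least 2 points")
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid <= 0) or np.any(np.diff(t_grid) <= 0):
        raise InvalidArgumentError("t_grid must be positive strictly increasing")
    bounds = np.asarray(bounds, dtype=float)[:2]
    area = float(np.prod(bounds[:, 1] - bounds[:, 0]))

    if correction == "none":
        d = np.sort(pdist(coords))
        pair_counts = 2.0 * np.searchsorted(d, t_grid, side="right")
        k_hat = area / (n * (n - 1)) * pair_counts
    elif correction == "border":
        border = np.minimum(
            np.min(coords - bounds[:, 0], axis=1),
            np.min(bounds[:, 1] - coords, axis=1),
        )
        from scipy.spatial.distance import squareform

        dm = squareform(pdist(coords))
        np.fill_diagonal(dm, np.inf)
        k_hat = np.empty(t_grid.size)
        for i, t in enumerate(t_grid):
            ok = border >= t
            m = int(ok.sum())
            if m == 0:
                k_hat[i] = np.nan
                continue
            k_hat[i] = area / (m * (n - 1)) * np.sum(dm[ok] <= t)
    else:
        raise InvalidArgumentError(f"unknown correction {correction!r}")
    return np.sqrt(k_hat / np.pi)


def ripley_curves(
    coords: np.ndarray, labels, bounds, t_grid, correction: str = "none"
) -> CurveSet:
    """Per-type L curves of a labeled point set (types with < 2 points
    are skipped)."""
    labels = np.asarray(labels)
    curves = {}
    for t in np.unique(labels):
        pts = coords[labels == t]
        if pts.shape[0] >= 2:
            curves[str(t)] = ripley_l(pts, bounds, t_grid, correction)
    return CurveSet(distances=np.asarray(t_grid, dtype=float), curves=curves)


def curve_cosine(curve_a, curve_b) -> float:
    """Cosine similarity of two L-curves sampled on the same grid;
    NaN (with a warning) if either is the zero vector."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("curves must share the distance grid")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("cosine similarity undefined for a zero curve")
        return float("nan")
    return float(a @ b / (na * nb))


# --------------------------------------------------------------------------
# ligand-receptor set agreement


@dataclass
class RankedLRSet:
    """Ranked set of ligand-receptor pair identifiers.

    Ranks run 1..|set| by descending score; score ties are broken by
    input order (stable), so ranks are always a permutation.
    """

    pairs: list[str]
    scores: np.ndarray

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise InvalidArgumentError("pairs must be unique")
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size != len(self.pairs):
            raise InvalidArgumentError("scores must match pairs")
        order = np.argsort(-self.scores, kind="stable")
        self.ranks = np.empty(len(self.pairs), dtype=int)
        self.ranks[order] = np.arange(1, len(self.pairs) + 1)
        self._rank_of = dict(zip(self.pairs, self.ranks.tolist()))

    def __len__(self) -> int:
        return len(self.pairs)

    def rank_of(self, pair: str) -> int:
        return self._rank_of[pair]


def si(set_a, set_b) -> float:
    """Similarity index: |A ∩ B| / min(|A|, |B|) (size-corrected Jaccard)."""
    a = set(set_a)
    b = set(set_b)
    if not a or not b:
        raise InvalidArgumentError("sets must be non-empty")
    return len(a & b) / min(len(a), len(b))


def rsi(ranked_a: RankedLRSet, ranked_b: RankedLRSet) -> float:
    """Rank-based similarity of the shared pairs C = A ∩ B:

        RSI = 1 - (1/|C|) * sum_i | R_A(i)/|A| - R_B(i)/|B| |

    NaN (with a warning) when the overlap is empty.
    """
    common = sorted(set(ranked_a.pairs) & set(ranked_b.pairs))
    if not common:
        warnings.warn("RSI undefined for an empty overlap")
        return float("nan")
    disp = [
        abs(ranked_a.rank_of(p) / len(ranked_a) - ranked_b.rank_of(p) / len(ranked_b))
        for p in common
    ]
    return float(1.0 - np.mean(disp))
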