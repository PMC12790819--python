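"""Spatial-pattern targets: proportions, transition matrices, layer fields.

A :class:`PatternSpec` is the target a simulation aims for — global
cell-type proportions ``pi`` (length K, sums to 1) and a row-stochastic
K x K transition matrix ``P`` whose entry (i, j) is the probability that a
neighbor of a type-i cell has type j.  Specs come from three places:

* predefined modes (attractive / repulsive / layered / gyrus, plus three
  tumor-immune-microenvironment presets),
* estimation from a labeled spatial dataset (:func:`estimate_pattern`),
* user-supplied matrices.

The layered and gyrus modes additionally carry a :class:`LayerLayout`
describing geometric strata; :func:`layered_labels` samples a label field
from it (each layer draws its dominant type with probability
``dominant_prob`` and spreads the rest uniformly).

Feasibility note: on a roughly degree-regular graph the realized neighbor
counts are symmetric, so the achievable transition matrices satisfy the
balance condition ``pi_i * P_ij ~= pi_j * P_ji``.  Presets shipped here
respect that balance; arbitrary user targets are optimized best-effort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidArgumentError
from .plate import CellPlate, NeighborGraph

_ATOL = 1e-9

PREDEFINED_MODES = (
    "custom",
    "attractive",
    "repulsive",
    "layered",
    "gyrus",
    "time_cold",
    "time_mixed",
    "time_compartmentalized",
)


@dataclass
class PatternSpec:
    """Target proportions and neighbor transition matrix for K cell types."""

    proportions: np.ndarray
    transition: np.ndarray
    mode: str = "custom"
    type_names: list[str] | None = None

    def __post_init__(self):
        pi = np.asarray(self.proportions, dtype=float).ravel()
        P = np.asarray(self.transition, dtype=float)
        if self.mode not in PREDEFINED_MODES:
            raise InvalidArgumentError(f"unknown mode {self.mode!r}")
        if P.shape != (pi.size, pi.size):
            raise InvalidArgumentError("transition must be K x K matching proportions")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > _ATOL:
            raise InvalidArgumentError("proportions must be >= 0 and sum to 1")
        if np.any(P < -_ATOL) or np.any(P > 1 + _ATOL):
            raise InvalidArgumentError("transition entries must lie in [0, 1]")
        rows = P.sum(axis=1)
        # all-zero rows are allowed (estimated isolated types), flagged upstream
        bad = np.abs(rows - 1.0) > _ATOL
        if np.any(bad & (rows != 0)):
            raise InvalidArgumentError("transition rows must sum to 1 (or be all-zero)")
        self.proportions = pi
        self.transition = P
        if self.type_names is None:
            self.type_names = [str(i) for i in range(pi.size)]
        elif len(self.type_names) != pi.size:
            raise InvalidArgumentError("type_names length must equal K")

    @property
    def n_types(self) -> int:
        return self.proportions.size

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "type_names": list(self.type_names),
            "proportions": self.proportions.tolist(),
            "transition": self.transition.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PatternSpec":
        return cls(
            proportions=np.asarray(d["proportions"], dtype=float),
            transition=np.asarray(d["transition"], dtype=float),
            mode=d.get("mode", "custom"),
            type_names=list(d["type_names"]) if "type_names" in d else None,
        )

    def save(self, path) -> None:
        """Write as JSON (canonical dialect)."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "PatternSpec":
        """Read a spec from JSON, YAML, or TOML, keyed by file suffix."""
        path = Path(path)
        text = path.read_text()
        suffix = path.suffix.lower()
        if suffix in (".yaml", ".yml"):
            import yaml

            d = yaml.safe_load(text)
        elif suffix == ".toml":
            import tomllib

            d = tomllib.loads(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d)


@dataclass
class LayerLayout:
    """Geometric strata along one plate axis.

    ``boundaries`` are the strictly increasing internal break positions
    along axis ``axis`` (n_layers - 1 of them).  Gyrus folding displaces
    the effective axis coordinate by ``amplitude * sin(2*pi*frequency *
    u)`` where ``u`` is the orthogonal coordinate rescaled to [0, 1].
    """

    n_layers: int
    boundaries: np.ndarray
    axis: int = 1
    dominant_prob: float = 0.8
    amplitude: float = 0.0
    frequency: float = 1.0

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float).ravel()
        if self.n_layers < 1 or b.size != self.n_layers - 1:
            raise InvalidArgumentError("need n_layers - 1 boundaries")
        if b.size and np.any(np.diff(b) <= 0):
            raise InvalidArgumentError("boundaries must be strictly increasing")
        if not 0 < self.dominant_prob <= 1:
            raise InvalidArgumentError("dominant_prob must be in (0, 1]")
        self.boundaries = b

    @classmethod
    def equal_strata(
        cls, plate: CellPlate, n_layers: int, axis: int = 1, **kw
    ) -> "LayerLayout":
        lo, hi = plate.bounds[axis]
        edges = np.linspace(lo, hi, n_layers + 1)[1:-1]
        return cls(n_layers=n_layers, boundaries=edges, axis=axis, **kw)

    def layer_of(self, plate: CellPlate) -> np.ndarray:
        """Layer index of every cell (gyrus folding applied if set)."""
        coord = plate.coords[:, self.axis].copy()
        if self.amplitude != 0.0 and plate.dim >= 2:
            other = 1 - self.axis if self.axis < 2 else 0
            lo, hi = plate.bounds[other]
            u = (plate.coords[:, other] - lo) / (hi - lo)
            coord = coord + self.amplitude * np.sin(2 * np.pi * self.frequency * u)
        return np.searchsorted(self.boundaries, coord, side="right")


def predefined_pattern(
    mode: str,
    n_types: int,
    group_assignment: Sequence[Sequence[int]] | None = None,
    dominant_prob: float = 0.8,
    proportions=None,
    type_names: list[str] | None = None,
) -> PatternSpec:
    """Build a predefined :class:`PatternSpec`.

    Modes
    -----
    attractive
        Each type clusters with itself: diagonal ``dominant_prob``,
        off-diagonal mass uniform, ``(1 - dominant_prob) / (K - 1)``.
    repulsive
        Types stay within their group (given by ``group_assignment``, a
        partition of ``range(K)`` into >= 2 groups): within-group mass
        ``dominant_prob`` split uniformly over the group (self included),
        the residual split uniformly over the remaining types.
    layered / gyrus
        Transition matrix implied by stratified multinomial sampling with
        per-layer dominant probability ``dominant_prob`` (one layer per
        type), assuming neighbors share a layer; pair with
        :func:`layered_labels` for the geometric field.
    time_cold / time_mixed / time_compartmentalized
        Two-type (tumor, immune) microenvironment presets; see
        :data:`TIME_PRESETS`.  Package defaults, editable after creation.
    """
    K = int(n_types)
    if K < 1:
        raise InvalidArgumentError("n_types must be >= 1")
    if not 0 < dominant_prob <= 1:
        raise InvalidArgumentError("dominant_prob must be in (0, 1]")

    if mode.startswith("time_"):
        return _time_preset(mode)

    if proportions is None:
        pi = np.full(K, 1.0 / K)
    else:
        pi = np.asarray(proportions, dtype=float)

    if mode == "attractive":
        if K < 2:
            raise InvalidArgumentError("attractive mode requires K >= 2")
        P = np.full((K, K), (1.0 - dominant_prob) / (K - 1))
        np.fill_diagonal(P, dominant_prob)
    elif mode == "repulsive":
        if K < 2:
            raise InvalidArgumentError("repulsive mode requires K >= 2")
        if group_assignment is None or len(group_assignment) < 2:
            raise InvalidArgumentError("repulsive mode requires >= 2 groups")
        groups = [list(g) for g in group_assignment]
        if any(len(g) == 0 for g in groups):
            raise InvalidArgumentError("empty group in group_assignment")
        if sorted(t for g in groups for t in g) != list(range(K)):
            raise InvalidArgumentError("group_assignment must partition range(K)")
        P = np.zeros((K, K))
        for g in groups:
            others = [t for t in range(K) if t not in g]
            for i in g:
                P[i, g] = dominant_prob / len(g)
                if others:
                    P[i, others] = (1.0 - dominant_prob) / len(others)
                else:  # single group would not be repulsive; guarded above
                    P[i, g] = 1.0 / len(g)
    elif mode in ("layered", "gyrus"):
        P = _layered_transition(K, dominant_prob)
    else:
        raise InvalidArgumentError(f"unknown predefined mode {mode!r}")

    return PatternSpec(proportions=pi, transition=P, mode=mode, type_names=type_names)


def _layered_transition(K: int, p: float) -> np.ndarray:
    """Implied transition matrix of K equal strata, one dominant type each.

    Within layer l the type distribution is q_l (p on the dominant type,
    (1-p)/(K-1) elsewhere).  Assuming neighbors share a layer,
    P(j | i) = sum_l Pr(layer=l | type=i) q_l[j] with Pr(l | i) ∝ q_l[i].
    """
    if K == 1:
        return np.ones((1, 1))
    q = np.full((K, K), (1.0 - p) / (K - 1))  # q[l, j]
    np.fill_diagonal(q, p)
    # Pr(l | i) = q[l, i] / sum_l' q[l', i]; equal layer widths
    w = q / q.sum(axis=0, keepdims=True)  # w[l, i]
    return w.T @ q


# Two-type tumor/immune presets. Proportions and matrices are package
# defaults chosen to satisfy the defining structural features (cold: scarce
# immune cells, strongly self-adherent tumor; mixed: immune cells
# interspersed through tumor, high cross-type transitions; compartmentalized:
# abundant immune cells segregated from tumor, high self-transitions for
# both) and the neighbor-count balance pi_i P_ij = pi_j P_ji.
TIME_PRESETS: dict[str, dict] = {
    "time_cold": {
        "proportions": [0.9, 0.1],
        "transition": [[0.95, 0.05], [0.45, 0.55]],
    },
    "time_mixed": {
        "proportions": [0.6, 0.4],
        "transition": [[0.6, 0.4], [0.6, 0.4]],
    },
    "time_compartmentalized": {
        "proportions": [0.6, 0.4],
        "transition": [[0.9, 0.1], [0.15, 0.85]],
    },
}


def _time_preset(mode: str) -> PatternSpec:
    if mode not in TIME_PRESETS:
        raise InvalidArgumentError(f"unknown TIME preset {mode!r}")
    d = TIME_PRESETS[mode]
    return PatternSpec(
        proportions=np.asarray(d["proportions"]),
        transition=np.asarray(d["transition"]),
        mode=mode,
        type_names=["tumor", "immune"],
    )


def layered_labels(
    plate: CellPlate,
    layout: LayerLayout,
    type_per_layer: Mapping[int, int] | Sequence[int] | None = None,
    n_types: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Sample a layered label field.

    Each cell draws its type from a multinomial: the layer's dominant type
    with probability ``layout.dominant_prob``, the remaining mass uniform
    over the other K - 1 types.  Gyrus folds are honored through
    ``layout.layer_of``.
    """
    if type_per_layer is None:
        type_per_layer = list(range(layout.n_layers))
    dominant = np.asarray(
        [type_per_layer[l] for l in range(layout.n_layers)], dtype=int
    )
    K = int(n_types) if n_types is not None else int(dominant.max()) + 1
    if np.any(dominant < 0) or np.any(dominant >= K):
        raise InvalidArgumentError("dominant type out of range")
    p = layout.dominant_prob
    rng = np.random.default_rng(seed)
    layer = layout.layer_of(plate)
    labels = np.empty(plate.n_cells, dtype=int)
    if K == 1:
        labels[:] = 0
        return labels
    probs = np.full((layout.n_layers, K), (1.0 - p) / (K - 1))
    probs[np.arange(layout.n_layers), dominant] = p
    u = rng.random(plate.n_cells)
    cum = np.cumsum(probs, axis=1)
    for l in range(layout.n_layers):
        m = layer == l
        labels[m] = np.searchsorted(cum[l], u[m], side="right")
    np.clip(labels, 0, K - 1, out=labels)
    return labels


def estimate_pattern(
    graph: NeighborGraph,
    labels,
    n_types: int | None = None,
    type_names: list[str] | None = None,
) -> PatternSpec:
    """Estimate (pi, P) from a labeled spatial dataset.

    ``pi_hat`` is the empirical type frequency; ``P_hat`` row-normalizes
    the neighbor-type count matrix ``X^T A X``.  Types with no graph
    neighbors yield all-zero rows, left as zeros with a warning.

    ``labels`` may be integers or strings; string labels are encoded in
    sorted order and recorded in ``type_names``.
    """
    labels = np.asarray(labels)
    if labels.size != graph.n_cells:
        raise InvalidArgumentError("labels and graph must have matching N")
    if labels.dtype.kind in "iu":
        codes = labels.astype(int)
        K = int(n_types) if n_types is not None else int(codes.max()) + 1
        names = type_names or [str(i) for i in range(K)]
    else:
        names = sorted(np.unique(labels).tolist())
        lookup = {t: i for i, t in enumerate(names)}
        codes = np.asarray([lookup[t] for t in labels])
        K = len(names)

    pi = np.bincount(codes, minlength=K).astype(float)
    pi /= pi.sum()

    counts = transition_counts(codes, graph.adjacency, K)
    rows = counts.sum(axis=1)
    P = np.zeros((K, K))
    nz = rows > 0
    P[nz] = counts[nz] / rows[nz, None]
    if np.any(~nz):
        warnings.warn(
            "types with no neighbors leave all-zero transition rows: "
            + ", ".join(str(names[i]) for i in np.nonzero(~nz)[0]),
            stacklevel=2,
        )
    return PatternSpec(proportions=pi, transition=P, mode="custom", type_names=list(map(str, names)))


def transition_counts(codes: np.ndarray, adjacency, K: int) -> np.ndarray:
    """Neighbor-type endpoint count matrix ``X^T A X`` (dense K x K)."""
    import scipy.sparse as sp

    X = sp.csr_matrix(
        (np.ones(codes.size), (np.arange(codes.size), codes)), shape=(codes.size, K)
    )
    return np.asarray((X.T @ adjacency @ X).todense(), dtype=float)
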