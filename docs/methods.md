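# Methods

This note documents the models, algorithms, and numerical choices behind
`stforge`, and what its synthetic data do and do not emulate.

## The assignment model

A spatial pattern over K cell types is parameterized by global
proportions π and a row-stochastic transition matrix P, where P_ij is
the probability that a neighbor of a type-i cell has type j. Given N
coordinates and a symmetric binary adjacency A, the simulator seeks the
one-hot labeling X minimizing ‖P − C⁻¹XᵀAX‖_F subject to one label per
cell and exact per-type counts π·N. XᵀAX counts *edge endpoints* (each
undirected edge contributes to both ordered type pairs), C row-normalizes
it. Rows of XᵀAX that are all zero (a type with no graph neighbors) are
left as zero rows and flagged rather than raising: the objective then
charges that row the full mass of P's row.

**Feasibility.** Because the endpoint count matrix is symmetric, any
realizable transition matrix obeys the balance condition
c_i P̂_ij = c_j P̂_ji, where c_i is the total degree mass of type i
(≈ π_i on a degree-regular graph). Targets violating this balance — e.g.
π = (0.8, 0.2) with P₁₂ large — are optimized best-effort; the shipped
presets and the regime matrices used in tests satisfy it, which is why
their final objectives approach zero.

## Annealers

All three strategies use the same Metropolis core, written once and
JIT-compiled: moves exchange the labels of two units of different types
(counts are invariant by construction), the endpoint count matrix is
updated incrementally per relabeling (exactness is tested against full
recomputation at 1e-10), and the incumbent best is returned rather than
the final state.

Temperature schedule (the field standard; exposed in `AnnealSchedule`):
T₀ is the mean |ΔE| over 100 random probe swaps, cooling is geometric
with α = 0.95, and the run stops at 10⁻⁴·T₀, after 200 consecutive
rejected proposals, or after 400 temperature steps; one proposal per
unit per step.

- **GSA** anneals cells directly; initial labels are a random
  permutation of the exact target multiset.
- **LSA** cuts the plate into g × g grids with g = ⌈√(N/1000)⌉, anneals
  each grid independently against the global (π, P) with per-grid seed
  streams, concatenates, then recalibrates to the exact global counts
  (per-grid rounding can leave a few units of drift).
- **BSA** uses M = max(1, ⌊½·log₂(N/1000)⌋ + 1) epochs (clamped to 1
  below N = 1000, where the formula goes non-positive). The finest zone
  grid has ⌈N^¼⌉ windows per axis (≈ √N zones); in epoch m the window
  edge lengths are the finest dimensions times 2^(M−m), and each move
  bundles 2^m swaps. Epoch 1 draws one label per window from
  Categorical(π); children windows inherit their parent's label. Zone
  annealing runs on the zone contact graph W = BᵀAB (B the cell-to-zone
  incidence; diagonal entries carry intra-zone edge mass), which makes
  the zone-level energy an exact coarse-graining of the cell-level
  energy for zone-constant labelings. After the last epoch, zone labels
  expand to cells, counts are recalibrated exactly, and a full-plate
  cell-level refinement pass runs (count-preserving swaps, so the
  recalibrated counts are final).

Recalibration switches uniformly chosen surplus-type cells to deficient
types; it deliberately ignores geometry — the refinement pass, not the
recalibration, restores spatial coherence. Integer targets come from
largest-remainder apportionment with ties to the lowest type index.

## Neighborhood graphs

kNN nominates each cell's k nearest neighbors (ties at the k-th distance
broken by lowest index for reproducibility) and symmetrizes by union,
since the objective treats A as undirected; note the union degree has no
2k upper bound — a point may be among the k nearest of arbitrarily many
others. Radius graphs use strict d < r. Delaunay uses the triangulation
edges (Euclidean geometry; co-circular point sets may tie-break either
diagonal). SNN connects kNN candidates sharing at least one common kNN
neighbor (threshold configurable). Cosine and Manhattan metrics operate
on raw coordinates; cosine degenerates (and errors) when all points
share a direction through the origin. Coordinates are continuous reals
in 2D or 3D; the zone hierarchy partitions the first two axes.

## Predefined patterns

- *attractive*: diagonal `dominant_prob` (default 0.8), off-diagonal
  uniform.
- *repulsive*: requires a partition of the types into ≥ 2 groups;
  within-group mass `dominant_prob` split uniformly over the group
  including self, residual split uniformly over the remaining types
  (the prose description admits several readings; this is the simplest
  row-stochastic one).
- *layered / gyrus*: labels are sampled geometrically — equal strata
  along one axis, each with a dominant type drawn with probability 0.8
  and the rest uniform. The gyrus fold displaces the stratum coordinate
  by a sine wave (amplitude and frequency configurable; the simplest
  periodic fold, chosen because only the qualitative "convoluted
  boundary" property matters). The accompanying PatternSpec carries the
  transition matrix implied by within-layer mixing.
- *TIME presets* (`time_cold`, `time_mixed`, `time_compartmentalized`):
  two-type tumor/immune matrices. These numbers are package defaults
  chosen to satisfy the defining structural features (cold: scarce,
  excluded immune cells; mixed: interspersed, high cross-type
  transitions; compartmentalized: abundant but segregated immune cells)
  and the balance condition above; they are editable after creation.

The two-type regime matrices used by the phenomenology tests follow the
same logic at π = (0.8, 0.2): mixed [[0.8, 0.2], [0.8, 0.2]],
compartmentalized [[0.9, 0.1], [0.4, 0.6]], layered
[[0.95, 0.05], [0.2, 0.8]]. Balance forces the majority type's
self-transition ≥ 0.75 at these proportions, so "low self-transition"
in the mixed regime applies to the minority type; the expected same-type
edge fractions (0.68, 0.84, 0.92) are strictly ordered, which is the
property asserted.

## Expression

Reference sampling draws, for each cell, a uniformly chosen reference
cell of the same type *with replacement* (so the simulated N may exceed
the reference size); provenance is recorded per cell. The parametric
simulator draws negative-binomial counts as a gamma-Poisson mixture with
variance μ + μ²/θ (θ the dispersion, default 2), baseline mean 2, and
20 disjoint marker genes per type upregulated 8-fold — defaults sized so
marker-based type separation is unambiguous but not trivial. Optional
independent zero-inflation is off by default.

The built-in layered-cortex fixture has 1234 cells in six types (141
astrocytes, 150 endothelial, 258 eL2/3, 198 eL4, 287 eL6, 200
oligodendrocytes) on the unit square: the three excitatory populations
occupy three y-strata (by rank of the y coordinate, so the counts are
exact), the other three types are dispersed uniformly, and expression
comes from the NB simulator. It emulates laminar organization and
marker structure only — not real marker genes, spatial expression
gradients within a type, segmentation noise, or library-size variation —
so tests passing on it demonstrate algorithmic correctness, not fidelity
to any particular tissue.

## Spot aggregation

Square or hexagonal lattices of circular or rectangular spots, pitch
equal to the spot diameter/side (abutting, never overlapping), keeping
only spots fully inside the bounds. Membership is by cell center:
half-open [min, max) intervals per axis for rectangles (a cell on a
shared edge belongs to exactly one spot, so rectangle tilings capture
every in-bounds cell exactly once) and strict interior for circles
(lattice gaps leave uncaptured cells, which are counted and reported).
Spot counts are exact integer sums over member cells; compositions are
emitted as both counts and proportions.

## Metrics

ARI and NMI are computed from the contingency table by their standard
formulas (NMI with the arithmetic-mean normalizer, natural log — the
value is base-invariant; two identical one-cluster partitions define
NMI = 1); both are cross-checked against scikit-learn at 1e-9. The CSM
columns are group degree centrality, mean member local clustering
coefficient (averaged over group members, the reading consistent with a
per-group score), and group closeness as reachable-non-member count over
summed shortest-path distances (unreachable nodes excluded with a
warning); cross-checked against networkx. NEM counts edge endpoints,
shuffles labels with the graph fixed (default 1000 permutations,
seeded; an exhaustive mode enumerates the label multiset for tiny
inputs), and normalizes by the population standard deviation; σ = 0
with x = μ gives z = 0.

Ripley's K uses K̂(t) = |A|/(n(n−1)) Σ 1[d_ij ≤ t] and L = √(K̂/π),
with CSR baseline L(t) = t. No edge correction is applied by default
because the curves are used comparatively on matched geometry, where the
shared bias cancels; the uncorrected estimator is biased low near the
boundary, so the calibration test against the theoretical CSR baseline
uses the border-corrected (reduced-sample) estimator instead. SI is
|A∩B|/min(|A|,|B|); RSI is one minus the mean normalized rank
displacement over the overlap, with score ties broken stably by input
order so ranks are always a permutation.

## Problem sizes and determinism

The test and acceptance workloads use N = 2000 for the two-type runs,
N = 5000 for transition-matrix recovery, 99 replicates of n = 500 for
the CSR envelope, and N ≤ 10 for the enumeration oracle — sizes at which
the annealer's behavior is already asymptotic while whole-suite runs
stay interactive. All randomness descends from a single integer seed
through named SeedSequence spawns (per-grid LSA streams, per-epoch BSA
streams), so identical configurations reproduce outputs byte for byte.

## Known limitations

- The transition matrix is spatially invariant; boundary-dependent or
  spatially varying transition structure is out of scope.
- Simulated annealing offers no optimality guarantee; infeasible
  targets (balance-violating P) terminate at a best-effort objective.
- The NB expression model has no gene-gene correlation, batch effects,
  or library-size variation.
- Spot membership is by cell center; area-overlap capture is not
  modeled.
- Zone windows partition the first two axes only; 3D plates get
  columnar zones (cell-level refinement is fully 3D-aware).
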