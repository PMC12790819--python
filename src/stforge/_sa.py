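"""Numba kernels for count-preserving simulated annealing on label fields.

The state is a label vector over *units* (cells, or zones during the
batched hierarchy) living on a weighted graph given in CSR form.  The
tracked statistic is the weighted neighbor-type count matrix
``M = X^T W X`` (K x K); the energy is the Frobenius distance between the
row-normalization of ``M`` and a target transition matrix ``P``.  Moves
exchange the labels of two units of different types, so per-type unit
counts are invariant by construction.  ``M`` is updated incrementally on
every (un)relabeling; a move bundles ``swaps_per_move`` exchanges that are
accepted or rejected together under the Metropolis rule.

Self-loops in the graph (diagonal weights, used for intra-zone edge mass
at the zone level) contribute to the diagonal of ``M`` only.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def energy(M, P):
    """Frobenius norm of ``P - rownorm(M)``; all-zero rows of M contribute
    the corresponding row of P (consistent with the flagged-zero-row
    convention of transition_frequency)."""
    K = M.shape[0]
    tot = 0.0
    for i in range(K):
        s = 0.0
        for j in range(K):
            s += M[i, j]
        for j in range(K):
            if s > 0.0:
                d = P[i, j] - M[i, j] / s
            else:
                d = P[i, j]
            tot += d * d
    return np.sqrt(tot)


@njit(cache=False)
def relabel(u, new, labels, indptr, indices, weights, M):
    """Switch unit ``u`` to label ``new``, updating ``M`` in place."""
    old = labels[u]
    for p in range(indptr[u], indptr[u + 1]):
        v = indices[p]
        wt = weights[p]
        if v == u:
            M[old, old] -= wt
            M[new, new] += wt
        else:
            c = labels[v]
            M[old, c] -= wt
            M[c, old] -= wt
            M[new, c] += wt
            M[c, new] += wt
    labels[u] = new


@njit(cache=False)
def _pick_pair(labels, n):
    # rejection sampling for a cross-type pair; gives up when labels are
    # (effectively) uniform
    for _ in range(200):
        u = np.random.randint(0, n)
        v = np.random.randint(0, n)
        if labels[u] != labels[v]:
            return u, v
    return -1, -1


@njit(cache=False)
def anneal(
    labels,
    indptr,
    indices,
    weights,
    M,
    P,
    swaps_per_move,
    moves_per_temp,
    alpha,
    tmin_frac,
    stall_limit,
    max_temps,
    seed,
    t0_probes,
):
    """Metropolis annealing with geometric cooling.

    T0 is calibrated to the mean |dE| over ``t0_probes`` random probe
    swaps; cooling multiplies by ``alpha`` per temperature step; the run
    stops at ``tmin_frac * T0``, after ``stall_limit`` consecutive
    rejected proposals, or after ``max_temps`` steps.  Returns the
    best-so-far incumbent, its energy, the number of temperature steps,
    and per-step traces of incumbent energy and acceptance rate.
    ``labels`` and ``M`` are left at the *current* (not best) state.
    """
    np.random.seed(seed)
    n = labels.shape[0]
    E = energy(M, P)
    best_E = E
    best_labels = labels.copy()

    us = np.empty(swaps_per_move, dtype=np.int64)
    vs = np.empty(swaps_per_move, dtype=np.int64)
    lus = np.empty(swaps_per_move, dtype=np.int64)
    lvs = np.empty(swaps_per_move, dtype=np.int64)

    acc = 0.0
    cnt = 0
    for _ in range(t0_probes):
        u, v = _pick_pair(labels, n)
        if u < 0:
            break
        lu = labels[u]
        lv = labels[v]
        relabel(u, lv, labels, indptr, indices, weights, M)
        relabel(v, lu, labels, indptr, indices, weights, M)
        E2 = energy(M, P)
        acc += abs(E2 - E)
        cnt += 1
        relabel(v, lv, labels, indptr, indices, weights, M)
        relabel(u, lu, labels, indptr, indices, weights, M)
    T0 = acc / cnt if cnt > 0 and acc > 0.0 else 1e-3
    T = T0

    trace = np.full(max_temps, np.nan)
    acc_rate = np.zeros(max_temps)
    n_temps = 0
    stall = 0
    while n_temps < max_temps:
        accepted = 0
        for _ in range(moves_per_temp):
            ns = 0
            for _s in range(swaps_per_move):
                u, v = _pick_pair(labels, n)
                if u < 0:
                    break
                us[ns] = u
                vs[ns] = v
                lus[ns] = labels[u]
                lvs[ns] = labels[v]
                relabel(u, lvs[ns], labels, indptr, indices, weights, M)
                relabel(v, lus[ns], labels, indptr, indices, weights, M)
                ns += 1
            if ns == 0:
                stall = stall_limit
                break
            E2 = energy(M, P)
            dE = E2 - E
            if dE <= 0.0 or np.random.random() < np.exp(-dE / T):
                E = E2
                accepted += 1
                stall = 0
                if E < best_E - 1e-15:
                    best_E = E
                    best_labels[:] = labels
            else:
                for s in range(ns - 1, -1, -1):
                    relabel(vs[s], lvs[s], labels, indptr, indices, weights, M)
                    relabel(us[s], lus[s], labels, indptr, indices, weights, M)
                stall += 1
                if stall >= stall_limit:
                    break
        trace[n_temps] = best_E
        acc_rate[n_temps] = accepted / moves_per_temp
        n_temps += 1
        if stall >= stall_limit:
            break
        T *= alpha
        if T < tmin_frac * T0:
            break
    return best_labels, best_E, n_temps, trace, acc_rate
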