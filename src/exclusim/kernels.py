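"""Numba-compiled inner loop of the lattice Markov chain.

Everything here operates on a raw ``int8`` grid plus scalar parameters so the
per-step cost stays at the sub-microsecond level; the readable reference
implementation of the same transition law lives in :mod:`exclusim.dynamics`
and the two are cross-checked statistically in the test suite.

Randomness: each chain seeds numba's thread-local NumPy legacy generator once
(``seed_kernel_rng``) and then draws from a single stream, so a run is fully
reproducible from its integer seed (same-seed/same-build contract).

Event codes returned by the resolvers:
  0 no-op (quiescence / stay-empty / border selection)
  1 death of the occupant
  2 migration out of the selected occupied vertex
  3 birth of a cell at the selected empty vertex
  4 migration into the selected empty vertex (the source is vacated)
"""

from __future__ import annotations

import numpy as np
from numba import njit

EV_NONE, EV_DEATH, EV_MIGRATE_OUT, EV_BIRTH, EV_MIGRATE_IN = 0, 1, 2, 3, 4

# Scratch sizing: rings have at most 4*d sites; d <= 8 is ample.
_MAX_RING = 64


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _can_place(grid, L, r, c, t, dmat, ig_r, ig_c):
    """Indicator I(t): may a type-t cell occupy empty (r, c) admissibly?

    (ig_r, ig_c) names one site whose occupant is disregarded (the migrating
    cell); pass (-1, -1) for none.  Border vertices are never placeable.
    """
    if r <= 0 or c <= 0 or r >= L - 1 or c >= L - 1:
        return False
    radius = max(dmat[t, 1], dmat[t, 2]) - 1
    rlo = r - radius if r - radius > 0 else 0
    rhi = r + radius if r + radius < L - 1 else L - 1
    for rr in range(rlo, rhi + 1):
        rem = radius - abs(rr - r)
        clo = c - rem if c - rem > 0 else 0
        chi = c + rem if c + rem < L - 1 else L - 1
        for cc in range(clo, chi + 1):
            u = grid[rr, cc]
            if u > 0 and not (rr == ig_r and cc == ig_c):
                if abs(rr - r) + abs(cc - c) < dmat[t, u]:
                    return False
    return True


@njit(cache=True, inline="always")
def _ring_fill(r, c, d, L, rows, cols):
    """Write in-grid sites at L1 distance d from (r, c) into rows/cols; return count."""
    n = 0
    for dr in range(-d, d + 1):
        rr = r + dr
        if rr < 0 or rr >= L:
            continue
        rem = d - abs(dr)
        if rem == 0:
            rows[n] = rr
            cols[n] = c
            n += 1
        else:
            cc = c - rem
            if cc >= 0:
                rows[n] = rr
                cols[n] = cc
                n += 1
            cc = c + rem
            if cc < L:
                rows[n] = rr
                cols[n] = cc
                n += 1
    return n


@njit(cache=True, inline="always")
def _resolve_occupied(grid, L, r, c, dmat, alpha, delta, rho, rows, cols, rec_r, rec_c):
    """Sample and apply one update at the occupied vertex (r, c).

    Returns (event_code, cell_type).  Outcome law: quiescence with
    probability alpha_i/Q, death with rho_i/Q, migration to each of the n_e
    admissible empty ring destinations with delta_i/Q each, where
    Q = alpha_i + n_e*delta_i + rho_i.
    """
    t = grid[r, c]
    a = alpha[t]
    de = delta[t]
    ro = rho[t]
    d = dmat[t, t]
    u = np.random.random()
    # Exact short-circuit: Q lies in [a+ro, a+ro+4*d*de] whatever n_e is, so
    # many draws decide the outcome before the receiver ring is inspected.
    qmax = a + ro + 4 * d * de
    if u * qmax < a:
        return EV_NONE, t  # quiescence for every possible n_e
    if u * (a + ro) >= a and u * qmax < a + ro:
        grid[r, c] = 0  # death for every possible n_e
        return EV_DEATH, t
    nring = _ring_fill(r, c, d, L, rows, cols)
    ne = 0
    for k in range(nring):
        rr, cc = rows[k], cols[k]
        if grid[rr, cc] == 0 and _can_place(grid, L, rr, cc, t, dmat, r, c):
            rec_r[ne] = rr
            rec_c[ne] = cc
            ne += 1
    q = a + ne * de + ro
    v = u * q
    if v < a:
        return EV_NONE, t
    if v < a + ro:
        grid[r, c] = 0
        return EV_DEATH, t
    k = int((v - a - ro) / de)
    if k >= ne:
        k = ne - 1
    grid[r, c] = 0
    grid[rec_r[k], rec_c[k]] = t
    return EV_MIGRATE_OUT, t


@njit(cache=True, inline="always")
def _resolve_empty(grid, L, r, c, dmat, alpha, delta, rho, rows, cols, don_r, don_c):
    """Sample and apply one update at the empty vertex (r, c).

    Outcome law: stay empty with (rho_1 + rho_2)/R; birth of type i with
    n_i*alpha_i*I(i)/R; migration of one of the n_i ring donors of type i
    into (r, c) with delta_i*I(i)/R each (the chosen source is vacated).
    R = rho_1 + rho_2 + sum_i n_i*(alpha_i + delta_i)*I(i).
    """
    if r <= 0 or c <= 0 or r >= L - 1 or c >= L - 1:
        return EV_NONE, 0
    n1 = 0
    n2 = 0
    i1 = _can_place(grid, L, r, c, 1, dmat, -1, -1)
    if i1:
        nring = _ring_fill(r, c, dmat[1, 1], L, rows, cols)
        for k in range(nring):
            if grid[rows[k], cols[k]] == 1:
                don_r[n1] = rows[k]
                don_c[n1] = cols[k]
                n1 += 1
    i2 = _can_place(grid, L, r, c, 2, dmat, -1, -1)
    if i2:
        nring = _ring_fill(r, c, dmat[2, 2], L, rows, cols)
        for k in range(nring):
            if grid[rows[k], cols[k]] == 2:
                don_r[_MAX_RING + n2] = rows[k]
                don_c[_MAX_RING + n2] = cols[k]
                n2 += 1
    rr0 = rho[1] + rho[2]
    w_b1 = n1 * alpha[1]
    w_m1 = n1 * delta[1]
    w_b2 = n2 * alpha[2]
    w_m2 = n2 * delta[2]
    big_r = rr0 + w_b1 + w_m1 + w_b2 + w_m2
    u = np.random.random() * big_r
    if u < rr0:
        return EV_NONE, 0
    u -= rr0
    if u < w_b1:
        grid[r, c] = 1
        return EV_BIRTH, 1
    u -= w_b1
    if u < w_m1:
        k = np.random.randint(0, n1)
        grid[don_r[k], don_c[k]] = 0
        grid[r, c] = 1
        return EV_MIGRATE_IN, 1
    u -= w_m1
    if u < w_b2:
        grid[r, c] = 2
        return EV_BIRTH, 2
    k = np.random.randint(0, n2)
    grid[don_r[_MAX_RING + k], don_c[_MAX_RING + k]] = 0
    grid[r, c] = 2
    return EV_MIGRATE_IN, 2


@njit(cache=True)
def resolve_vertex(grid, r, c, dmat, alpha, delta, rho):
    """Resolve one selected vertex, occupied or empty. Returns (code, type).

    Convenience entry point (allocates its own scratch); the run loop uses
    the preallocated-scratch variants.
    """
    L = grid.shape[0]
    rows = np.empty(_MAX_RING, dtype=np.int64)
    cols = np.empty(_MAX_RING, dtype=np.int64)
    aux_r = np.empty(2 * _MAX_RING, dtype=np.int64)
    aux_c = np.empty(2 * _MAX_RING, dtype=np.int64)
    if grid[r, c] > 0:
        return _resolve_occupied(grid, L, r, c, dmat, alpha, delta, rho, rows, cols, aux_r, aux_c)
    return _resolve_empty(grid, L, r, c, dmat, alpha, delta, rho, rows, cols, aux_r, aux_c)


@njit(cache=True)
def run_chain(grid, dmat, alpha, delta, rho, n_steps, step_offset, record_steps, out_counts):
    """Advance the chain n_steps from step_offset, recording cell counts.

    record_steps: sorted absolute step indices at which to record (a record
    at step s reflects the state after s total steps).  out_counts is a
    (len(record_steps), 2) int64 array receiving (n_tumor, n_normal).
    The caller seeds the kernel RNG; counts are maintained incrementally.
    """
    L = grid.shape[0]
    rows = np.empty(_MAX_RING, dtype=np.int64)
    cols = np.empty(_MAX_RING, dtype=np.int64)
    aux_r = np.empty(2 * _MAX_RING, dtype=np.int64)
    aux_c = np.empty(2 * _MAX_RING, dtype=np.int64)
    n1 = 0
    n2 = 0
    for r in range(L):
        for c in range(L):
            if grid[r, c] == 1:
                n1 += 1
            elif grid[r, c] == 2:
                n2 += 1
    n_rec = record_steps.shape[0]
    rec_i = 0
    while rec_i < n_rec and record_steps[rec_i] < step_offset:
        rec_i += 1  # already recorded by an earlier chunk
    while rec_i < n_rec and record_steps[rec_i] == step_offset:
        out_counts[rec_i, 0] = n1
        out_counts[rec_i, 1] = n2
        rec_i += 1
    for s in range(step_offset + 1, step_offset + n_steps + 1):
        r = np.random.randint(0, L)
        c = np.random.randint(0, L)
        if grid[r, c] > 0:
            code, t = _resolve_occupied(
                grid, L, r, c, dmat, alpha, delta, rho, rows, cols, aux_r, aux_c
            )
        else:
            code, t = _resolve_empty(
                grid, L, r, c, dmat, alpha, delta, rho, rows, cols, aux_r, aux_c
            )
        if code == EV_DEATH:
            if t == 1:
                n1 -= 1
            else:
                n2 -= 1
        elif code == EV_BIRTH:
            if t == 1:
                n1 += 1
            else:
                n2 += 1
        while rec_i < n_rec and record_steps[rec_i] == s:
            out_counts[rec_i, 0] = n1
            out_counts[rec_i, 1] = n2
            rec_i += 1
    return n1, n2
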