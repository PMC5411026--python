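"""Numba kernels for the lattice update and toxin deposition.

The update is a fixed-step random-sequential kinetic Monte Carlo sweep:
each step, all active sites (C, C_on, X) are visited in a freshly
randomized order.  Daughters created during a sweep do not act until the
next sweep.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# C-cell program selector for a step
C_STOCHASTIC = 0  # replicate + stochastic switching
C_GROW_ONLY = 1   # replicate, no switching (sync grow phase, non-lysing variant)
C_INERT = 2       # neither replicate nor switch (sync pause phase)

_OFFS = np.array(
    [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)],
    dtype=np.int64,
)
# first four are orthogonal (weight 1), last four diagonal (weight diag_factor)


@njit(cache=True, inline="always")
def _deposit(toxin, kern, oi, oj):
    """Add the exponential profile centred at (oi, oj); kern centre is (n-1, m-1)."""
    n, m = toxin.shape
    a0 = n - 1 - oi
    b0 = m - 1 - oj
    for a in range(n):
        for b in range(m):
            toxin[a, b] += kern[a0 + a, b0 + b]


@njit(cache=True)
def deposit_kernel(toxin, kern, oi, oj):
    _deposit(toxin, kern, oi, oj)


@njit(cache=True)
def release_all_c(grid, toxin, kern):
    """Collective toxin release: every C (or C_on) site lyses and deposits."""
    n, m = grid.shape
    for i in range(n):
        for j in range(m):
            g = grid[i, j]
            if g == 1 or g == 2:
                grid[i, j] = 0
                _deposit(toxin, kern, i, j)


@njit(cache=True)
def step_kernel(grid, toxin, born, order, offs, kern,
                p_rep_c, p_rep_x, diag_factor, p_switch, p_lyse, sigma_dt,
                c_mode, deposit_on_rep, lysis_enabled, rng):
    """One random-sequential sweep.  Mutates grid/toxin in place.

    p_rep_c / p_rep_x are r*dt (per unit neighbor weight); sigma_dt is
    sigma_x*dt.  born and order are scratch buffers (uint8 n*m and int64
    >= n*m).
    """
    n, m = grid.shape
    count = 0
    for i in range(n):
        for j in range(m):
            born[i, j] = 0
            g = grid[i, j]
            if g == 1 or g == 2 or g == 3:
                order[count] = i * m + j
                count += 1
    # Fisher-Yates shuffle of the active-site list
    for k in range(count - 1, 0, -1):
        r = rng.integers(0, k + 1)
        tmp = order[k]
        order[k] = order[r]
        order[r] = tmp

    emp_i = np.empty(8, dtype=np.int64)
    emp_j = np.empty(8, dtype=np.int64)

    for k in range(count):
        idx = order[k]
        i = idx // m
        j = idx % m
        if born[i, j] == 1:
            continue
        g = grid[i, j]
        if g == 2:
            # producing cell: can only lyse (never replicates, never reverts)
            if lysis_enabled and rng.random() < p_lyse:
                grid[i, j] = 0
                _deposit(toxin, kern, i, j)
            continue
        if g == 3:
            tox = toxin[i, j]
            if sigma_dt > 0.0 and tox > 0.0:
                if rng.random() < -np.expm1(-sigma_dt * tox):
                    grid[i, j] = 4
                    continue
        elif g == 1:
            if c_mode == C_INERT:
                continue
        else:
            continue
        # replication of a viable C or X cell
        w = 0.0
        ne = 0
        for q in range(8):
            ii = i + offs[q, 0]
            jj = j + offs[q, 1]
            if 0 <= ii < n and 0 <= jj < m and grid[ii, jj] == 0:
                w += 1.0 if q < 4 else diag_factor
                emp_i[ne] = ii
                emp_j[ne] = jj
                ne += 1
        if ne > 0:
            p = (p_rep_c if g == 1 else p_rep_x) * w
            if rng.random() < p:
                t = rng.integers(0, ne)
                grid[emp_i[t], emp_j[t]] = g
                born[emp_i[t], emp_j[t]] = 1
                if g == 1 and deposit_on_rep:
                    _deposit(toxin, kern, i, j)
        if g == 1 and c_mode == C_STOCHASTIC and p_switch > 0.0:
            if rng.random() < p_switch:
                grid[i, j] = 2
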