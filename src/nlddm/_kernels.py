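"""Compiled inner loops: Euler–Maruyama trial batches and the Crank–Nicolson
tridiagonal time stepper.  Model dispatch uses an integer code (0 = DDM,
1 = nl-DDM) so a single kernel serves both drift laws."""
from __future__ import annotations

import numpy as np
from numba import njit

DDM_CODE = 0
NLDDM_CODE = 1


@njit(cache=True, inline="always")
def _drift(code, c1, c2, c3, x):
    # DDM: c1 = nu.  nl-DDM: c1 = k, c2 = a, c3 = z.
    if code == DDM_CODE:
        return c1
    return -c1 * (x + c2) * (x - c3) * (x - c2)


@njit(cache=True)
def sim_trials(code, c1, c2, c3, sigma, bound, starts, dt, n_steps, seed):
    """Simulate one decision per start; returns (decision_time, outcome).

    outcome: +1 upper boundary (correct), -1 lower (error), 0 undecided.
    Decision times exclude the non-decision offset.
    """
    np.random.seed(seed)
    n = starts.shape[0]
    rts = np.full(n, np.nan)
    outcomes = np.zeros(n, dtype=np.int64)
    s = sigma * np.sqrt(dt)
    for i in range(n):
        x = starts[i]
        for j in range(n_steps):
            x += _drift(code, c1, c2, c3, x) * dt + s * np.random.standard_normal()
            if x >= bound:
                outcomes[i] = 1
                rts[i] = (j + 1) * dt
                break
            if x <= -bound:
                outcomes[i] = -1
                rts[i] = (j + 1) * dt
                break
    return rts, outcomes


@njit(cache=True)
def sim_path(code, c1, c2, c3, sigma, bound, start, dt, noise):
    """Single trajectory on pre-drawn standard-normal increments.

    Returns (states, n_kept, outcome); states[0] is the starting point and
    the path is truncated at the first grid point at/past a boundary.
    """
    n_steps = noise.shape[0]
    states = np.empty(n_steps + 1)
    states[0] = start
    s = sigma * np.sqrt(dt)
    x = start
    for j in range(n_steps):
        x += _drift(code, c1, c2, c3, x) * dt + s * noise[j]
        states[j + 1] = x
        if x >= bound:
            return states, j + 2, 1
        if x <= -bound:
            return states, j + 2, -1
    return states, n_steps + 1, 0


@njit(cache=True)
def cn_evolve(lower, diag, upper, p0, dt, n_steps, flux_lo_coef, flux_hi_coef):
    """Crank–Nicolson evolution of ``dp/dt = A p`` for tridiagonal ``A``.

    ``lower[i]`` couples node i to i-1, ``upper[i]`` to i+1.  Boundary fluxes
    are read off the time-midpoint state so the discrete balance
    ``mass_lost_per_step = (flux_lo + flux_hi) * dt`` holds to round-off.

    Returns (f_lo, f_hi, p_final): defective first-passage densities at the
    lower/upper absorbing ends, sampled at t = (n + 1/2) dt.
    """
    m = p0.shape[0]
    half = 0.5 * dt
    # M1 = I - (dt/2) A   (solved);   M2 = I + (dt/2) A   (applied)
    b = np.empty(m)
    for i in range(m):
        b[i] = 1.0 - half * diag[i]
    c = np.empty(m)
    a = np.empty(m)
    for i in range(m):
        c[i] = -half * upper[i]
        a[i] = -half * lower[i]
    # Thomas factorization of M1 (constant in time)
    w = np.empty(m)
    bp = np.empty(m)
    bp[0] = b[0]
    for i in range(1, m):
        w[i] = a[i] / bp[i - 1]
        bp[i] = b[i] - w[i] * c[i - 1]

    p = p0.copy()
    pn = np.empty(m)
    rhs = np.empty(m)
    y = np.empty(m)
    f_lo = np.empty(n_steps)
    f_hi = np.empty(n_steps)
    for n in range(n_steps):
        # rhs = M2 @ p
        for i in range(m):
            v = (1.0 + half * diag[i]) * p[i]
            if i > 0:
                v += half * lower[i] * p[i - 1]
            if i < m - 1:
                v += half * upper[i] * p[i + 1]
            rhs[i] = v
        # solve M1 pn = rhs
        y[0] = rhs[0]
        for i in range(1, m):
            y[i] = rhs[i] - w[i] * y[i - 1]
        pn[m - 1] = y[m - 1] / bp[m - 1]
        for i in range(m - 2, -1, -1):
            pn[i] = (y[i] - c[i] * pn[i + 1]) / bp[i]
        f_lo[n] = flux_lo_coef * 0.5 * (p[0] + pn[0])
        f_hi[n] = flux_hi_coef * 0.5 * (p[m - 1] + pn[m - 1])
        for i in range(m):
            p[i] = pn[i]
    return f_lo, f_hi, p
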