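"""Grid-search internals for the maximal information coefficient.

The search follows the ApproxMaxMI scheme: one axis is equipartitioned on
ranks into ``ny`` rows, and the cut placement on the other axis is optimised
exactly by dynamic programming over clump boundaries (positions where the
row membership of rank-consecutive points changes).  Both axis orientations
are evaluated, because the heuristic is not symmetric.

Tied values are never separated by a cut, so every score is a pure function
of the joint rank structure of the sample — strictly increasing transforms
of either variable leave all results bit-identical.

The numeric kernels compile with numba when it is importable and fall back
to pure Python otherwise (identical results, slower).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(func):
            return func

        return deco


@njit(cache=True)
def _dp_columns(cum, max_cols):
    """Exact DP over column-cut placements for a fixed row assignment.

    Parameters
    ----------
    cum : (m+1, R) float64
        Cumulative per-row point counts at the m clump boundaries
        (``cum[t, r]`` = points of row r among the first t clumps).
    max_cols : int
        Largest number of columns to score.

    Returns
    -------
    (max_cols+1,) float64 with ``out[l]`` = max over partitions of the clump
    sequence into at most ``l`` columns of ``sum_cols sum_rows c*log2(c/n_col)``
    (the negative weighted conditional-entropy term of the mutual information).
    """
    m = cum.shape[0] - 1
    R = cum.shape[1]
    # cost[s, t] = n_(s,t] * H(row | column spanning clumps s..t), in bits
    cost = np.zeros((m + 1, m + 1))
    for s in range(m + 1):
        for t in range(s + 1, m + 1):
            nst = 0.0
            for r in range(R):
                nst += cum[t, r] - cum[s, r]
            h = 0.0
            if nst > 0.0:
                for r in range(R):
                    d = cum[t, r] - cum[s, r]
                    if d > 0.0:
                        h -= d * np.log2(d / nst)
            cost[s, t] = h
    G = np.full((m + 1, max_cols + 1), -np.inf)
    for t in range(1, m + 1):
        G[t, 1] = -cost[0, t]
    for l in range(2, max_cols + 1):
        for t in range(1, m + 1):
            best = G[t, l - 1]  # fewer columns always admissible
            for s in range(1, t):
                v = G[s, l - 1] - cost[s, t]
                if v > best:
                    best = v
            G[t, l] = best
    out = np.empty(max_cols + 1)
    out[0] = -np.inf
    for l in range(1, max_cols + 1):
        out[l] = G[m, l]
    return out


@njit(cache=True)
def _scores_given_rows(xstart, rows, ny, max_nx, cap):
    """Max MI (bits) for 2..max_nx columns, given a fixed row assignment.

    Parameters
    ----------
    xstart : (Gx+1,) int64
        Start offsets of the column-axis tie groups in column-sorted point
        order; ``xstart[-1] == n``.  Cuts may fall only at these offsets.
    rows : (n,) int64
        Row index of each point, in column-sorted order.
    ny : int
        Number of rows (nominal; empty rows are allowed).
    max_nx : int
        Largest column count to score.
    cap : int
        Superclump budget: if the number of clumps exceeds ``cap`` (> 0),
        candidate boundaries are thinned to ~``cap`` by point mass.
        ``cap == 0`` disables thinning (exact search over the tie structure).

    Returns
    -------
    (max_nx+1,) float64; entry ``l`` is the best MI with at most ``l``
    columns (entries 0 and 1 are -1).
    """
    n = rows.shape[0]
    Gx = xstart.shape[0] - 1
    # --- clumps: merge adjacent pure tie groups sharing one row -------------
    bpos = np.empty(Gx + 1, np.int64)
    bpos[0] = 0
    nb = 1
    prev_pure = False
    prev_row = -1
    for g in range(Gx):
        lo = xstart[g]
        hi = xstart[g + 1]
        rmin = rows[lo]
        rmax = rows[lo]
        for i in range(lo + 1, hi):
            rr = rows[i]
            if rr < rmin:
                rmin = rr
            if rr > rmax:
                rmax = rr
        pure = rmin == rmax
        if g > 0 and not (pure and prev_pure and rmin == prev_row):
            bpos[nb] = lo
            nb += 1
        prev_pure = pure
        prev_row = rmax
    bpos[nb] = n
    m = nb
    b = bpos
    # --- superclumps: thin candidate boundaries to ~cap by point mass -------
    if cap > 1 and m > cap:
        nb2 = np.empty(cap + 1, np.int64)
        nb2[0] = 0
        k = 1
        bi = 1
        for j in range(1, cap):
            target = (j * n) // cap
            while bi < m and bpos[bi] <= target:
                bi += 1
            cand = bpos[bi - 1]  # largest boundary <= target
            if cand > nb2[k - 1]:
                nb2[k] = cand
                k += 1
        nb2[k] = n
        b = nb2
        m = k
    # --- cumulative row histogram at clump boundaries -----------------------
    cum = np.zeros((m + 1, ny))
    for k2 in range(m):
        for r in range(ny):
            cum[k2 + 1, r] = cum[k2, r]
        for i in range(b[k2], b[k2 + 1]):
            cum[k2 + 1, rows[i]] += 1.0
    hq = 0.0
    for r in range(ny):
        c = cum[m, r]
        if c > 0.0:
            hq -= (c / n) * np.log2(c / n)
    g2 = _dp_columns(cum, max_nx)
    out = np.empty(max_nx + 1)
    out[0] = -1.0
    if max_nx >= 1:
        out[1] = -1.0
    for l in range(2, max_nx + 1):
        out[l] = hq + g2[l] / n
    return out


def warm_up() -> None:
    """Trigger JIT compilation on a tiny problem (no-op without numba)."""
    xstart = np.array([0, 1, 2, 3, 4], dtype=np.int64)
    rows = np.array([0, 1, 0, 1], dtype=np.int64)
    _scores_given_rows(xstart, rows, 2, 2, 0)
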