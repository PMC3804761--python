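"""Pairwise association measures: MIC, PCC, and the extended MIC (eMIC).

The maximal information coefficient (MIC) scans grid partitions of the
scatterplot of two vectors: for a grid with ``x`` columns and ``y`` rows the
grid mutual information is normalized by ``log2 min(x, y)``, and MIC is the
maximum of that normalized score over all grids with ``x*y <= B``,
``B = floor(n**0.6)``.  The extended MIC subtracts the squared Pearson
correlation,

    eMIC = MIC - PCC**2,

leaving the non-linear component of the association.  eMIC is reported
signed: at finite n the heuristic MIC maximum can fall below PCC**2 and the
value is then (slightly) negative; it is never clipped.

The grid search is the ApproxMaxMI-style heuristic of :mod:`emicconn._mine`;
``mic(..., exhaustive=True)`` replaces the row equipartition by exhaustive
enumeration of row cuts (feasible for small n), which makes the search exact.
``mic_oracle`` is an independent brute-force enumeration used to validate
the exact search.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from ._mine import _scores_given_rows
from .errors import DegenerateInputError, SearchBudgetError

__all__ = [
    "PairedSample",
    "GridPartition",
    "AssociationScores",
    "grid_mutual_information",
    "normalized_grid_score",
    "mic",
    "pcc",
    "emic",
    "mic_oracle",
]

DEFAULT_EXPONENT = 0.6
DEFAULT_CLUMPS = 15
#: smallest admissible resolution budget: the 2x2 grid is always searched
MIN_B = 4


@dataclass(frozen=True)
class PairedSample:
    """An ordered sample of two real vectors of equal length."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1:
            raise ValueError("x and y must be one-dimensional")
        if x.shape[0] != y.shape[0]:
            raise ValueError(
                f"length mismatch: len(x)={x.shape[0]} len(y)={y.shape[0]}"
            )
        if x.shape[0] < 4:
            raise ValueError(f"need at least 4 paired observations, got {x.shape[0]}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("missing or non-finite values are not allowed")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass(frozen=True)
class GridPartition:
    """Interior cut points partitioning the axes of a scatterplot.

    ``x_edges`` (strictly increasing) split the x-axis into
    ``len(x_edges)+1`` columns; likewise ``y_edges`` for rows.  Any scored
    partition must have at least 2 columns and 2 rows.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray

    def __post_init__(self):
        xe = np.atleast_1d(np.asarray(self.x_edges, dtype=float))
        ye = np.atleast_1d(np.asarray(self.y_edges, dtype=float))
        for name, e in (("x_edges", xe), ("y_edges", ye)):
            if e.size < 1:
                raise ValueError(f"{name}: need at least one cut (2 cells per axis)")
            if e.size > 1 and not np.all(np.diff(e) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        object.__setattr__(self, "x_edges", xe)
        object.__setattr__(self, "y_edges", ye)

    @property
    def n_columns(self) -> int:
        return self.x_edges.size + 1

    @property
    def n_rows(self) -> int:
        return self.y_edges.size + 1


class AssociationScores(NamedTuple):
    """The four scores the measure family reports for one pair."""

    pcc: float
    pcc_squared: float
    mic: float
    emic: float


def _as_pair(x, y=None) -> PairedSample:
    if y is None:
        if isinstance(x, PairedSample):
            return x
        raise TypeError("pass a PairedSample, or two vectors x and y")
    return PairedSample(np.asarray(x), np.asarray(y))


def _check_variance(sample: PairedSample) -> None:
    if np.ptp(sample.x) == 0:
        raise DegenerateInputError("x has zero variance")
    if np.ptp(sample.y) == 0:
        raise DegenerateInputError("y has zero variance")


def resolution_budget(n: int, exponent: float = DEFAULT_EXPONENT) -> int:
    """Grid-cell budget B = floor(n**exponent), floored at 4 (2x2 grid)."""
    return max(MIN_B, int(math.floor(n**exponent)))


# ---------------------------------------------------------------------------
# grid mutual information (plug-in, base-2)
# ---------------------------------------------------------------------------


def grid_mutual_information(sample: PairedSample | Sequence, grid: GridPartition,
                            y=None) -> float:
    """Plug-in mutual information (bits) of the cell occupancy of ``grid``.

    MI(X;Y) = H(X) + H(Y) - H(X, Y) on the discrete distribution obtained by
    binning the sample into the grid's cells.
    """
    if y is not None:
        sample = _as_pair(sample, y)
    sample = _as_pair(sample)
    cols = np.searchsorted(grid.x_edges, sample.x, side="right")
    rows = np.searchsorted(grid.y_edges, sample.y, side="right")
    joint = np.bincount(
        cols * grid.n_rows + rows, minlength=grid.n_columns * grid.n_rows
    ).reshape(grid.n_columns, grid.n_rows)
    return _mi_from_counts(joint)


def _mi_from_counts(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint.ravel() / n
    px = joint.sum(axis=1) / n
    py = joint.sum(axis=0) / n
    h = stats.entropy(p, base=2)
    hx = stats.entropy(px, base=2)
    hy = stats.entropy(py, base=2)
    return float(hx + hy - h)


# ---------------------------------------------------------------------------
# heuristic / exact grid search
# ---------------------------------------------------------------------------


def _tie_groups(v: np.ndarray):
    """Stable sort order, per-point tie-group id, group starts and sizes."""
    order = np.argsort(v, kind="stable")
    sv = v[order]
    change = np.empty(v.shape[0], dtype=bool)
    change[0] = True
    change[1:] = sv[1:] != sv[:-1]
    gid_sorted = np.cumsum(change) - 1
    gid = np.empty(v.shape[0], dtype=np.int64)
    gid[order] = gid_sorted
    starts = np.flatnonzero(change).astype(np.int64)
    return order, gid, starts


def _axis_scores(col_vals, row_vals, B, clumps, exhaustive, only=None):
    """Best MI per grid shape with columns on the ``col_vals`` axis.

    Returns a dict ``{(n_cols, n_rows): mi_bits}``.  ``only`` restricts the
    scan to one ``(n_cols, n_rows)`` shape.
    """
    n = col_vals.shape[0]
    corder, _, cstarts = _tie_groups(col_vals)
    xstart = np.append(cstarts, n).astype(np.int64)
    rorder, rgid, rstarts = _tie_groups(row_vals)
    rgid_col = rgid[corder]
    Gy = rstarts.shape[0]
    out: dict[tuple[int, int], float] = {}
    max_ny = B // 2
    for ny in range(2, max_ny + 1):
        max_nx = B // ny
        if max_nx < 2:
            break
        if only is not None:
            if only[1] != ny:
                continue
            max_nx = only[0]
        if exhaustive:
            if Gy < ny:
                continue  # cannot place ny-1 cuts between distinct values
            for cuts in itertools.combinations(range(1, Gy), ny - 1):
                rowof = np.searchsorted(np.asarray(cuts), np.arange(Gy), side="right")
                rows = rowof[rgid_col].astype(np.int64)
                sc = _scores_given_rows(xstart, rows, ny, max_nx, 0)
                for nx in range(2, max_nx + 1):
                    key = (nx, ny)
                    if sc[nx] > out.get(key, 0.0):
                        out[key] = float(sc[nx])
        else:
            rowof = (rstarts * ny) // n  # rank equipartition, ties kept together
            rows = rowof[rgid_col].astype(np.int64)
            cap = int(clumps * max_nx) if clumps else 0
            sc = _scores_given_rows(xstart, rows, ny, max_nx, cap)
            for nx in range(2, max_nx + 1):
                key = (nx, ny)
                if sc[nx] > out.get(key, 0.0):
                    out[key] = float(sc[nx])
    return out


def normalized_grid_score(sample, x: int, y: int = None, *, nx: int = None,
                          ny: int = None, clumps: int = DEFAULT_CLUMPS,
                          exhaustive: bool | None = None,
                          max_cells: int = 1024) -> float:
    """m_{x×y}: best grid MI at resolution (x columns, y rows) / log2 min(x,y).

    ``exhaustive=None`` picks exhaustive row enumeration when the sample is
    small (n <= 12) and the rank-equipartition heuristic otherwise.  Grids
    with ``x*y > max_cells`` are refused.
    """
    if nx is None:
        nx = x
    if ny is None:
        ny = y if y is not None else x
    sample = _as_pair(sample)
    _check_variance(sample)
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 columns and 2 rows")
    if nx * ny > max_cells:
        raise SearchBudgetError(
            f"grid {nx}x{ny} exceeds the search budget of {max_cells} cells"
        )
    if exhaustive is None:
        exhaustive = sample.n <= 12
    best = 0.0
    s1 = _axis_scores(sample.x, sample.y, nx * ny, clumps, exhaustive, only=(nx, ny))
    best = max(best, s1.get((nx, ny), 0.0))
    if not exhaustive:
        # the heuristic is orientation-dependent; try the transpose too
        s2 = _axis_scores(sample.y, sample.x, nx * ny, clumps, False, only=(ny, nx))
        best = max(best, s2.get((ny, nx), 0.0))
    return min(best / math.log2(min(nx, ny)), 1.0)


def mic(sample, y=None, *, exponent: float = DEFAULT_EXPONENT,
        clumps: int = DEFAULT_CLUMPS, exhaustive: bool = False) -> float:
    """Maximal information coefficient of a paired sample.

    Scans all grids with ``x*y <= B = floor(n**exponent)`` (never below the
    2x2 grid), scoring each with the heuristic search of :mod:`._mine`; with
    ``exhaustive=True`` all row-cut placements are enumerated, which makes
    the value exact (intended for small n).
    """
    sample = _as_pair(sample, y)
    _check_variance(sample)
    B = resolution_budget(sample.n, exponent)
    cl = 0 if exhaustive else clumps
    s1 = _axis_scores(sample.x, sample.y, B, cl, exhaustive)
    s2 = _axis_scores(sample.y, sample.x, B, cl, exhaustive)
    best = 0.0
    for scores in (s1, s2):
        for (a, b), mi_bits in scores.items():
            v = mi_bits / math.log2(min(a, b))
            if v > best:
                best = v
    return min(best, 1.0)


def pcc(sample, y=None) -> float:
    """Pearson product-moment correlation coefficient."""
    sample = _as_pair(sample, y)
    _check_variance(sample)
    r = np.corrcoef(sample.x, sample.y)[0, 1]
    return float(min(1.0, max(-1.0, r)))


def emic(sample, y=None, *, exponent: float = DEFAULT_EXPONENT,
         clumps: int = DEFAULT_CLUMPS) -> AssociationScores:
    """All four scores for one pair; emic = mic - pcc**2 (signed, unclipped)."""
    sample = _as_pair(sample, y)
    r = pcc(sample)
    m = mic(sample, exponent=exponent, clumps=clumps)
    return AssociationScores(pcc=r, pcc_squared=r * r, mic=m, emic=m - r * r)


# ---------------------------------------------------------------------------
# brute-force oracle (independent of the DP path)
# ---------------------------------------------------------------------------


def mic_oracle(sample, y=None, *, exponent: float = DEFAULT_EXPONENT,
               max_n: int = 10) -> float:
    """Exhaustive-enumeration MIC for tiny samples (n <= ``max_n``).

    Every placement of column and row cuts between distinct sorted values is
    enumerated for every grid shape within the resolution budget, and the
    plug-in MI of the induced contingency table is normalized and maximized.
    This is a deliberately independent implementation (no dynamic
    programming) used as a reference for the exact search.
    """
    sample = _as_pair(sample, y)
    if sample.n > max_n:
        raise SearchBudgetError(
            f"oracle refuses n={sample.n} > {max_n} (combinatorial blow-up)"
        )
    _check_variance(sample)
    B = resolution_budget(sample.n, exponent)
    _, xgid, xstarts = _tie_groups(sample.x)
    _, ygid, ystarts = _tie_groups(sample.y)
    Gx, Gy = xstarts.shape[0], ystarts.shape[0]
    best = 0.0
    for nx in range(2, B // 2 + 1):
        if nx > Gx:
            break
        for nyy in range(2, B // nx + 1):
            if nyy > Gy:
                break
            denom = math.log2(min(nx, nyy))
            for xcuts in itertools.combinations(range(1, Gx), nx - 1):
                colof = np.searchsorted(np.asarray(xcuts), np.arange(Gx), side="right")
                cols = colof[xgid]
                for ycuts in itertools.combinations(range(1, Gy), nyy - 1):
                    rowof = np.searchsorted(
                        np.asarray(ycuts), np.arange(Gy), side="right"
                    )
                    rows = rowof[ygid]
                    joint = np.bincount(
                        cols * nyy + rows, minlength=nx * nyy
                    ).reshape(nx, nyy)
                    v = _mi_from_counts(joint) / denom
                    if v > best:
                        best = v
    return min(best, 1.0)
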