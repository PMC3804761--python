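"""Group-label Kendall tau edge ranking.

For edge values x_1..x_N with group labels +1 (m controls) / -1 (n patients),
only cross-group pairs are compared:

    tau = (n_c - n_d) / (m * n)

where a (control, patient) pair is concordant when the control's value is
the larger one.  tau > 0 therefore means the edge is *decreased* in the
patient group; tau < 0 means increased.  Tied cross-group pairs count toward
neither n_c nor n_d (the denominator stays m*n).  The discriminative power
of an edge is |tau|; edges are ranked by power with ties broken by edge
order, which makes the ranking deterministic.

``KendallTauSelector`` wraps top-k (or |tau|-threshold) selection as a
scikit-learn transformer so it can sit inside a Pipeline and be refit inside
each cross-validation fold without leaking the held-out subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "Direction",
    "RankedEdges",
    "kendall_tau_group",
    "group_tau_matrix",
    "rank_edges",
    "select_top_k",
    "KendallTauSelector",
]


class Direction(str, Enum):
    DECREASED_IN_PATIENTS = "decreased_in_patients"
    INCREASED_IN_PATIENTS = "increased_in_patients"
    TIED = "tied"


def direction_of(tau: float) -> Direction:
    if tau > 0:
        return Direction.DECREASED_IN_PATIENTS
    if tau < 0:
        return Direction.INCREASED_IN_PATIENTS
    return Direction.TIED


@dataclass(frozen=True)
class RankedEdges:
    """Per-edge tau, power = |tau|, rank order, and direction of change.

    ``order`` lists edge indices from most to least discriminative;
    ``rank[e]`` is edge e's 1-based rank.
    """

    tau: np.ndarray
    power: np.ndarray
    rank: np.ndarray
    order: np.ndarray
    directions: tuple[Direction, ...]

    @property
    def n_edges(self) -> int:
        return self.tau.shape[0]


def _split_groups(labels: np.ndarray):
    labels = np.asarray(labels, dtype=int)
    controls = labels == 1
    patients = labels == -1
    if not controls.any() or not patients.any():
        raise ValueError("both groups (+1 and -1) must be non-empty")
    return controls, patients


def kendall_tau_group(values, labels) -> float:
    """Cross-group Kendall tau of one edge; see the module docstring."""
    values = np.asarray(values, dtype=float)
    controls, patients = _split_groups(labels)
    diff = values[controls][:, None] - values[patients][None, :]
    nc = int((diff > 0).sum())
    nd = int((diff < 0).sum())
    return (nc - nd) / diff.size


def group_tau_matrix(matrix, labels) -> np.ndarray:
    """Cross-group Kendall tau of every column of a subjects x edges matrix."""
    matrix = np.asarray(matrix, dtype=float)
    controls, patients = _split_groups(labels)
    diff = matrix[controls][:, None, :] - matrix[patients][None, :, :]
    m, n = int(controls.sum()), int(patients.sum())
    return np.sign(diff).sum(axis=(0, 1)) / (m * n)


def rank_edges(table_or_matrix, labels=None) -> RankedEdges:
    """Rank all edges by discriminative power |tau|, descending.

    Accepts a :class:`~emicconn.connectivity.FeatureTable` or a raw
    subjects x edges matrix plus labels.  Ties in power are broken by edge
    index (stable), so the ranking is deterministic.
    """
    if labels is None:
        matrix, labels = table_or_matrix.matrix, table_or_matrix.labels
    else:
        matrix = np.asarray(table_or_matrix, dtype=float)
    tau = group_tau_matrix(matrix, labels)
    power = np.abs(tau)
    order = np.argsort(-power, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, order.shape[0] + 1)
    directions = tuple(direction_of(t) for t in tau)
    return RankedEdges(tau=tau, power=power, rank=rank, order=order,
                       directions=directions)


def select_top_k(ranked: RankedEdges, k: int = 200) -> np.ndarray:
    """Indices of the k most discriminative edges (deterministic order)."""
    if not 1 <= k <= ranked.n_edges:
        raise ValueError(f"k={k} out of range 1..{ranked.n_edges}")
    return ranked.order[:k].copy()


class KendallTauSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector ranking edges by group-label |tau|.

    Parameters
    ----------
    k : int or None, default 200
        Keep the k highest-power edges (ties broken by edge order).
    threshold : float or None
        Alternative selector: keep edges with |tau| >= threshold.  Exactly
        one of ``k`` and ``threshold`` must be set.

    Attributes
    ----------
    tau_ : per-edge cross-group Kendall tau
    power_ : |tau_|
    ranking_ : :class:`RankedEdges` for the fitted data
    """

    def __init__(self, k: int | None = 200, threshold: float | None = None):
        self.k = k
        self.threshold = threshold

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=2)
        if (self.k is None) == (self.threshold is None):
            raise ValueError("set exactly one of k and threshold")
        self.ranking_ = rank_edges(X, np.asarray(y, dtype=int))
        self.tau_ = self.ranking_.tau
        self.power_ = self.ranking_.power
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.ranking_.n_edges, dtype=bool)
        if self.k is not None:
            mask[select_top_k(self.ranking_, self.k)] = True
        else:
            mask[self.power_ >= self.threshold] = True
        return mask
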