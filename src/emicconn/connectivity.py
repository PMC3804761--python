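"""Connectivity matrices and the edge feature space.

Each subject yields a symmetric regions x regions matrix under one of the
measures ``pcc | pcc2 | mic | emic``.  The diagonal stores the measure's
self-value (pcc/pcc2/mic = 1, emic = 0) but is never vectorized: features
are the upper-triangle entries in row-major (i < j) order, so R regions give
R(R-1)/2 features (116 regions -> 6670).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association
from .errors import DegenerateInputError, ManifestError
from .preprocess import RegionalTimeSeries

logger = logging.getLogger(__name__)

MEASURES = ("pcc", "pcc2", "mic", "emic")

__all__ = [
    "MEASURES",
    "ConnectivityMatrix",
    "EdgeIndex",
    "FeatureTable",
    "build_connectivity",
    "vectorize",
    "devectorize",
    "cohort_features",
    "group_mean_connectivity",
]

_SELF_VALUE = {"pcc": 1.0, "pcc2": 1.0, "mic": 1.0, "emic": 0.0}


@dataclass(frozen=True)
class EdgeIndex:
    """Canonical ordering of the upper-triangle edges of an R-region matrix:
    (0,1), (0,2), ..., (0,R-1), (1,2), ... with 0-based region indices."""

    n_regions: int

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")

    @property
    def n_edges(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    def pairs(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n_regions, k=1)
        return list(zip(iu[0].tolist(), iu[1].tolist()))

    def __len__(self) -> int:
        return self.n_edges


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric association matrix of one subject under one measure."""

    values: np.ndarray
    measure: str
    region_labels: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; use one of {MEASURES}")
        labels = tuple(str(l) for l in self.region_labels)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("values must be a square matrix")
        if values.shape[0] != len(labels):
            raise ValueError("one label per region is required")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_labels", labels)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x edges matrix with group labels (+1 control, -1 patient)."""

    matrix: np.ndarray
    subject_ids: tuple[str, ...]
    labels: np.ndarray
    edge_index: EdgeIndex
    measure: str
    region_labels: tuple[str, ...] = ()

    def __post_init__(self):
        matrix = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        ids = tuple(str(s) for s in self.subject_ids)
        if matrix.ndim != 2:
            raise ValueError("matrix must be subjects x edges")
        if matrix.shape[0] != len(ids) or matrix.shape[0] != labels.shape[0]:
            raise ValueError("one row, id, and label per subject is required")
        if matrix.shape[1] != self.edge_index.n_edges:
            raise ValueError(
                f"{matrix.shape[1]} columns but edge index has "
                f"{self.edge_index.n_edges} edges"
            )
        if not np.isfinite(matrix).all():
            raise ValueError("missing values are not allowed")
        if not set(np.unique(labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 (control) or -1 (patient)")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(
            self, "region_labels", tuple(str(l) for l in self.region_labels)
        )

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return self.matrix.shape[1]


def _edge_value(x: np.ndarray, y: np.ndarray, measure: str) -> float:
    if measure == "pcc":
        return association.pcc(x, y)
    if measure == "pcc2":
        return association.pcc(x, y) ** 2
    if measure == "mic":
        return association.mic(x, y)
    scores = association.emic(x, y)
    return scores.emic


def build_connectivity(series: RegionalTimeSeries, measure: str) -> ConnectivityMatrix:
    """Pairwise association matrix of one subject under ``measure``.

    A constant (zero-variance) region cannot support any of the measures;
    its edges are set to 0 with a logged warning.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; use one of {MEASURES}")
    if series.n_regions < 3:
        raise ValueError("need at least 3 regions")
    R = series.n_regions
    values = np.full((R, R), _SELF_VALUE[measure])
    data = series.data
    degenerate = [r for r in range(R) if np.ptp(data[r]) == 0]
    if degenerate:
        logger.warning(
            "regions with zero variance mapped to edge value 0: %s",
            [series.region_labels[r] for r in degenerate],
        )
    degenerate_set = set(degenerate)
    for i in range(R):
        for j in range(i + 1, R):
            if i in degenerate_set or j in degenerate_set:
                v = 0.0
            else:
                v = _edge_value(data[i], data[j], measure)
            values[i, j] = values[j, i] = v
    return ConnectivityMatrix(values, measure, series.region_labels)


def vectorize(matrix: ConnectivityMatrix) -> np.ndarray:
    """Upper-triangle edge vector in canonical ``EdgeIndex`` order."""
    iu = np.triu_indices(matrix.n_regions, k=1)
    return matrix.values[iu]


def devectorize(vector: np.ndarray, measure: str, region_labels) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize` (diagonal restored to the self-value)."""
    vector = np.asarray(vector, dtype=float)
    R = len(region_labels)
    if vector.shape[0] != R * (R - 1) // 2:
        raise ValueError("vector length does not match the region count")
    values = np.full((R, R), _SELF_VALUE[measure])
    iu = np.triu_indices(R, k=1)
    values[iu] = vector
    values[(iu[1], iu[0])] = vector
    return ConnectivityMatrix(values, measure, tuple(region_labels))


def cohort_features(subjects, labels, measure: str,
                    subject_ids=None) -> FeatureTable:
    """Stack per-subject edge vectors into a subjects x edges feature table.

    Parameters
    ----------
    subjects : sequence of RegionalTimeSeries (all sharing region labels)
    labels : per-subject +1 (control) / -1 (patient)
    measure : one of ``pcc | pcc2 | mic | emic``
    """
    subjects = list(subjects)
    if not subjects:
        raise ManifestError("empty cohort")
    ref = subjects[0].region_labels
    offending = [
        i for i, s in enumerate(subjects) if s.region_labels != ref
    ]
    if offending:
        raise ManifestError(
            f"subjects at positions {offending} have region labels differing "
            "from the first subject's"
        )
    if subject_ids is None:
        subject_ids = [f"sub{i:03d}" for i in range(len(subjects))]
    rows = [vectorize(build_connectivity(s, measure)) for s in subjects]
    return FeatureTable(
        np.vstack(rows), tuple(subject_ids), np.asarray(labels, dtype=int),
        EdgeIndex(len(ref)), measure, ref,
    )


def group_mean_connectivity(table: FeatureTable, group: int):
    """Per-edge mean over one group plus scalar mean/sd over edges.

    ``group`` is +1 (controls) or -1 (patients).  Returns
    ``(edge_means, summary)`` where summary is a dict with the mean and
    standard deviation of the per-edge group-mean vector — the quantities a
    group-contrast bar plot of all edges depicts.
    """
    mask = table.labels == group
    if not mask.any():
        raise ValueError(f"no subjects with label {group:+d}")
    edge_means = table.matrix[mask].mean(axis=0)
    summary = {
        "mean": float(edge_means.mean()),
        "sd": float(edge_means.std(ddof=1)) if edge_means.size > 1 else 0.0,
    }
    return edge_means, summary
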