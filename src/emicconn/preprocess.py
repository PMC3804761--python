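"""Temporal preprocessing of regional BOLD time series.

Order of the standard pipeline (spatial steps — realignment, normalization,
smoothing — are assumed already done or irrelevant for synthetic data):

1. discard the first k volumes (magnetic saturation),
2. remove each region's least-squares linear trend,
3. Chebyshev Type-I band-pass filter, 0.01–0.08 Hz,
4. regress out the six rigid-body motion parameters.

The band-pass is an order-4 Chebyshev I design with 0.5 dB passband ripple
applied forward-backward (``sosfiltfilt``), i.e. zero-phase: lag sensitivity
is precisely the weakness of zero-lag correlation measures, so the filter
must not introduce phase distortion of its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "RegionalTimeSeries",
    "MotionParameters",
    "discard_initial_volumes",
    "detrend_linear",
    "bandpass_chebyshev",
    "regress_motion",
    "regional_average",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class RegionalTimeSeries:
    """One subject's regions x timepoints matrix with region labels.

    Typical resting-state sessions retain well over 20 volumes; very short
    series are permitted (some operations need them) but most of the
    pipeline is only meaningful at realistic lengths.
    """

    data: np.ndarray
    region_labels: tuple[str, ...]
    tr_seconds: float = 2.0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D regions x timepoints matrix")
        labels = tuple(str(l) for l in self.region_labels)
        if data.shape[0] != len(labels):
            raise ValueError(
                f"{data.shape[0]} rows but {len(labels)} region labels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if data.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if not np.isfinite(data).all():
            raise ValueError("missing or non-finite values are not allowed")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "region_labels", labels)

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RegionalTimeSeries":
        return replace(self, data=data)


@dataclass(frozen=True)
class MotionParameters:
    """Six rigid-body head-motion regressors (3 translations, 3 rotations)."""

    data: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] != 6:
            raise ValueError("motion parameters must be a 6 x timepoints matrix")
        if not np.isfinite(data).all():
            raise ValueError("missing or non-finite values are not allowed")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def discard_initial_volumes(series: RegionalTimeSeries, k: int = 5) -> RegionalTimeSeries:
    """Drop the first ``k`` volumes (e.g. 180 acquired -> 175 retained)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= series.n_timepoints:
        raise ValueError(
            f"cannot discard {k} of {series.n_timepoints} timepoints"
        )
    if k == 0:
        return series
    return series.with_data(series.data[:, k:])


def detrend_linear(series: RegionalTimeSeries) -> RegionalTimeSeries:
    """Remove each region's least-squares linear trend (and mean)."""
    if series.n_timepoints < 3:
        raise ValueError("detrending needs at least 3 timepoints")
    return series.with_data(signal.detrend(series.data, axis=1, type="linear"))


def bandpass_chebyshev(series: RegionalTimeSeries, low_hz: float = 0.01,
                       high_hz: float = 0.08, order: int = 4,
                       ripple_db: float = 0.5) -> RegionalTimeSeries:
    """Zero-phase Chebyshev Type-I band-pass filter.

    Defaults keep the canonical resting-state band 0.01–0.08 Hz at TR = 2 s.
    """
    nyquist = 0.5 / series.tr_seconds
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist} Hz)"
        )
    sos = signal.cheby1(order, ripple_db, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / series.tr_seconds, output="sos")
    return series.with_data(signal.sosfiltfilt(sos, series.data, axis=1))


def regress_motion(series: RegionalTimeSeries, motion: MotionParameters) -> RegionalTimeSeries:
    """Replace each region by the residual of regression on the 6 motion
    regressors plus an intercept.

    Collinear (rank-deficient) regressor sets are handled by the
    minimum-norm least-squares solution; a warning is logged since dropped
    directions mean the motion model was redundant.
    """
    if motion.n_timepoints != series.n_timepoints:
        raise ValueError(
            f"motion has {motion.n_timepoints} timepoints, series has "
            f"{series.n_timepoints}"
        )
    X = np.column_stack([np.ones(series.n_timepoints), motion.data.T])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "motion regressors are rank-deficient (rank %d of %d); "
            "collinear directions carry no extra correction", rank, X.shape[1]
        )
    beta, *_ = np.linalg.lstsq(X, series.data.T, rcond=None)
    resid = series.data.T - X @ beta
    return series.with_data(resid.T)


def regional_average(voxel_data: np.ndarray, labels) -> RegionalTimeSeries:
    """Average voxel time series into regional mean time series.

    Parameters
    ----------
    voxel_data : voxels x timepoints matrix
    labels : sequence of region names, one per voxel (file order defines the
        region order: first occurrence wins)
    """
    voxel_data = np.asarray(voxel_data, dtype=float)
    labels = [str(l) for l in labels]
    if voxel_data.shape[0] != len(labels):
        raise ValueError("one label per voxel row is required")
    region_order = list(dict.fromkeys(labels))
    rows = []
    for region in region_order:
        idx = [i for i, l in enumerate(labels) if l == region]
        if not idx:
            raise ValueError(f"region {region!r} has no voxels")
        rows.append(voxel_data[idx].mean(axis=0))
    return RegionalTimeSeries(np.vstack(rows), tuple(region_order))


def preprocess_pipeline(series: RegionalTimeSeries,
                        motion: MotionParameters | None = None, *,
                        discard: int = 5, detrend: bool = True,
                        band: tuple[float, float] | None = (0.01, 0.08)) -> RegionalTimeSeries:
    """Run discard -> detrend -> band-pass -> motion regression, logging the
    executed order."""
    steps = []
    if discard:
        series = discard_initial_volumes(series, discard)
        steps.append(f"discard({discard})")
    if detrend:
        series = detrend_linear(series)
        steps.append("detrend")
    if band is not None:
        series = bandpass_chebyshev(series, band[0], band[1])
        steps.append(f"bandpass{band}")
    if motion is not None:
        motion_use = motion
        if discard and motion.n_timepoints == series.n_timepoints + discard:
            motion_use = MotionParameters(motion.data[:, discard:])
        series = regress_motion(series, motion_use)
        steps.append("regress_motion")
    logger.info("preprocessing order: %s", " -> ".join(steps) or "none")
    return series
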