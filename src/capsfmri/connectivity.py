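"""Region-level functional connectivity.

Region time series are the arithmetic mean of the voxel series within each
atlas label; the functional-connectivity (FC) matrix is the N x N Pearson
correlation of those series, and the feature vector is its strictly lower
triangle in row-major order (length N(N-1)/2; 6670 for the 116-region AAL
parcellation). No Fisher z-transform is applied.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import AtlasParcellation, TimeSeriesVolume

__all__ = [
    "RegionTimeSeries",
    "FCMatrix",
    "UndefinedCorrelationError",
    "region_means",
    "pearson",
    "fc_matrix",
    "fc_features",
    "fc_matrix_from_features",
]


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (zero-variance input)."""


@dataclasses.dataclass
class RegionTimeSeries:
    """N x T matrix of region-mean series, rows ordered by sorted region id."""

    series: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=np.float64)
        self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
        if self.series.ndim != 2 or self.series.shape[0] != self.region_ids.size:
            raise ValueError("series must be N x T with one row per region id")


@dataclasses.dataclass
class FCMatrix:
    """Symmetric unit-diagonal Pearson correlation matrix over regions."""

    r: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        self.region_ids = np.asarray(self.region_ids, dtype=np.int64)
        n = self.region_ids.size
        if self.r.shape != (n, n):
            raise ValueError(f"FC matrix shape {self.r.shape} != ({n}, {n})")

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    def to_dataframe(self) -> pd.DataFrame:
        ids = [str(i) for i in self.region_ids]
        return pd.DataFrame(self.r, index=ids, columns=ids)


def region_means(vol: TimeSeriesVolume, atlas: AtlasParcellation) -> RegionTimeSeries:
    """Mean voxel series per atlas region (label 0 / background excluded)."""
    if atlas.labels.shape != vol.spatial_shape:
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match volume {vol.spatial_shape}"
        )
    ids = atlas.region_ids
    if ids.size == 0:
        raise ValueError("atlas has no positive labels")
    flat_labels = atlas.labels.reshape(-1)
    flat_data = vol.data.reshape(-1, vol.n_timepoints)
    series = np.empty((ids.size, vol.n_timepoints))
    for k, rid in enumerate(ids):
        mask = flat_labels == rid
        series[k] = flat_data[mask].mean(axis=0)
    return RegionTimeSeries(series, ids)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length series."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 3:
        raise ValueError("need length >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero-variance series has no correlation")
    return float(np.clip((dx * dy).sum() / (sx * sy), -1.0, 1.0))


def fc_matrix(rts: RegionTimeSeries) -> FCMatrix:
    """Pearson correlation matrix over the region series.

    Symmetry and a unit diagonal are enforced exactly; a constant region
    series is an error naming the offending region.
    """
    sd = rts.series.std(axis=1)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise UndefinedCorrelationError(
            f"region {int(rts.region_ids[bad[0]])} has a constant series"
        )
    r = np.corrcoef(rts.series)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, rts.region_ids)


def fc_features(m: FCMatrix) -> np.ndarray:
    """Strictly-lower-triangle entries in row-major (i > j) order."""
    i, j = np.tril_indices(m.n_regions, k=-1)
    return m.r[i, j].copy()


def fc_matrix_from_features(vec: np.ndarray, region_ids: np.ndarray) -> FCMatrix:
    """Inverse of :func:`fc_features` given symmetry and a unit diagonal."""
    region_ids = np.asarray(region_ids, dtype=np.int64)
    n = region_ids.size
    vec = np.asarray(vec, dtype=np.float64)
    if vec.size != n * (n - 1) // 2:
        raise ValueError(f"expected {n * (n - 1) // 2} entries, got {vec.size}")
    r = np.eye(n)
    i, j = np.tril_indices(n, k=-1)
    r[i, j] = vec
    r[j, i] = vec
    return FCMatrix(r, region_ids)
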