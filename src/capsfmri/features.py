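"""Per-voxel resting-state feature maps: DC, ReHo, ALFF and fALFF.

Degree centrality (DC) counts, for each voxel, the other voxels whose
time-series Pearson correlation exceeds a threshold (0.25 by default) on the
*signed* correlation — an anticorrelated voxel does not count. Regional
homogeneity (ReHo) is Kendall's coefficient of concordance W of a voxel's
series with its 7/19/27-neighborhood, computed on midranks without a tie
correction (ties are measure-zero for continuous data); neighborhoods are
truncated at the grid boundary rather than padded. ALFF sums the one-sided
DFT amplitudes over the 0.01-0.08 Hz band, and fALFF divides that by the
amplitude total over the whole spectrum (DC bin excluded by default).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .io import TimeSeriesVolume

__all__ = [
    "FeatureMap",
    "SpectrumConfig",
    "degree_centrality",
    "reho",
    "spectrum",
    "alff",
    "falff",
]

FEATURE_NAMES = ("alff", "falff", "reho", "dc")


@dataclasses.dataclass
class FeatureMap:
    """One subject's 3D scalar map for a single feature."""

    values: np.ndarray
    feature_name: str
    subject_id: str | None = None
    flags: np.ndarray | None = None  # voxels where the statistic degenerated

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"feature map must be 3D, got {self.values.ndim}D")


@dataclasses.dataclass
class SpectrumConfig:
    """Spectral band for ALFF/fALFF.

    ``power_mode`` sums squared amplitudes instead of amplitudes (the
    printed-equation variant); the default is the amplitude sum.
    """

    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    exclude_dc_bin: bool = True
    power_mode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 <= band_low < band_high")


def degree_centrality(
    vol: TimeSeriesVolume,
    threshold: float = 0.25,
    absolute: bool = False,
    chunk: int = 512,
) -> FeatureMap:
    """Count, per voxel, the other voxels correlated above ``threshold``.

    Expects band-passed input. Zero-variance voxels get DC = 0 and are
    flagged. ``absolute=True`` thresholds |r| instead of signed r.
    """
    if not -1.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (-1, 1), got {threshold}")
    shape = vol.spatial_shape
    X = vol.data.reshape(-1, vol.n_timepoints)
    sd = X.std(axis=1)
    valid = sd > 0.0
    if valid.sum() < 2:
        raise ValueError("need >= 2 voxels with nonzero variance")
    Z = np.zeros_like(X)
    Z[valid] = (X[valid] - X[valid].mean(axis=1, keepdims=True)) / (
        sd[valid, None] * np.sqrt(vol.n_timepoints)
    )
    counts = np.zeros(X.shape[0], dtype=np.int64)
    vidx = np.flatnonzero(valid)
    Zv = Z[vidx]
    for start in range(0, vidx.size, chunk):
        block = Zv[start : start + chunk] @ Zv.T  # correlations of block vs all valid
        if absolute:
            hits = np.abs(block) > threshold
        else:
            hits = block > threshold
        # self-correlation is exactly 1 and always exceeds a threshold < 1
        counts[vidx[start : start + chunk]] = hits.sum(axis=1) - 1
    counts[~valid] = 0
    flags = (~valid).reshape(shape)
    return FeatureMap(counts.reshape(shape).astype(np.float64), "dc", flags=flags)


_NEIGHBORHOOD_FOOTPRINTS = {}


def _footprint(neighborhood: int) -> np.ndarray:
    if neighborhood not in (7, 19, 27):
        raise ValueError(f"neighborhood must be one of 7, 19, 27; got {neighborhood}")
    if neighborhood not in _NEIGHBORHOOD_FOOTPRINTS:
        d = np.abs(np.mgrid[-1:2, -1:2, -1:2]).sum(axis=0)
        max_l1 = {7: 1, 19: 2, 27: 3}[neighborhood]
        _NEIGHBORHOOD_FOOTPRINTS[neighborhood] = (d <= max_l1).astype(np.float64)
    return _NEIGHBORHOOD_FOOTPRINTS[neighborhood]


def reho(vol: TimeSeriesVolume, neighborhood: int = 27) -> FeatureMap:
    """Kendall's W of each voxel's series with its spatial neighborhood.

    Expects band-passed, unsmoothed input. Boundary voxels use the truncated
    neighborhood inside the grid. W lies in [0, 1]: 1 for perfectly
    concordant rankings, 0 for (pairwise) reversed ones.
    """
    T = vol.n_timepoints
    if T < 4:
        raise ValueError(f"ReHo needs >= 4 time points, got {T}")
    fp = _footprint(neighborhood)[..., None]
    ranks = rankdata(vol.data, axis=3, method="average")
    # rank sum over the neighborhood, truncated at the boundary
    R = ndimage.correlate(ranks, fp, mode="constant", cval=0.0)
    K = ndimage.correlate(np.ones(vol.spatial_shape), fp[..., 0], mode="constant", cval=0.0)
    Rbar = R.mean(axis=3, keepdims=True)  # = K (T + 1) / 2 for midranks
    ss = ((R - Rbar) ** 2).sum(axis=3)
    denom = (K**2) * (T**3 - T) / 12.0
    W = np.clip(ss / denom, 0.0, 1.0)
    return FeatureMap(W, "reho")


def spectrum(series: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided DFT amplitude spectrum of a series.

    Returns ``(freqs, amplitudes)`` with bin h at frequency ``h * fs / T``
    for ``h = 0 .. floor(T/2)``.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.size < 8:
        raise ValueError("need a 1D series of length >= 8")
    amp = np.abs(np.fft.rfft(series))
    freqs = np.fft.rfftfreq(series.size, d=1.0 / fs)
    return freqs, amp


def _band_bins(T: int, fs: float, cfg: SpectrumConfig) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    band = (freqs >= cfg.band_low_hz) & (freqs <= cfg.band_high_hz)
    if not band.any():
        df = fs / T
        raise ValueError(
            f"band [{cfg.band_low_hz}, {cfg.band_high_hz}] Hz contains no DFT bin "
            f"for T={T}, fs={fs} (bin spacing {df:.6g} Hz)"
        )
    return freqs, band


def alff(vol: TimeSeriesVolume, cfg: SpectrumConfig | None = None) -> FeatureMap:
    """Amplitude of low-frequency fluctuation per voxel.

    Sum of one-sided DFT amplitudes over bins inside the closed band
    (squared amplitudes in ``power_mode``). Expects detrended, unfiltered
    input.
    """
    cfg = cfg or SpectrumConfig()
    _, band = _band_bins(vol.n_timepoints, vol.fs, cfg)
    amp = np.abs(np.fft.rfft(vol.data, axis=3))
    if cfg.power_mode:
        amp = amp**2
    values = amp[..., band].sum(axis=3)
    return FeatureMap(values, "alff")


def falff(vol: TimeSeriesVolume, cfg: SpectrumConfig | None = None) -> FeatureMap:
    """Fractional ALFF: in-band amplitude total over full-spectrum total.

    The DC bin is excluded from the denominator by default; constant series
    (zero total amplitude) are flagged and set to 0. Values lie in [0, 1].
    """
    cfg = cfg or SpectrumConfig()
    _, band = _band_bins(vol.n_timepoints, vol.fs, cfg)
    amp = np.abs(np.fft.rfft(vol.data, axis=3))
    if cfg.power_mode:
        amp = amp**2
    numer = amp[..., band].sum(axis=3)
    if cfg.exclude_dc_bin:
        denom = amp[..., 1:].sum(axis=3)
    else:
        denom = amp.sum(axis=3)
    flags = denom == 0.0
    if flags.any():
        warnings.warn(
            f"fALFF undefined for {int(flags.sum())} constant voxel(s); set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    values = np.zeros_like(numer)
    np.divide(numer, denom, out=values, where=~flags)
    values = np.clip(values, 0.0, 1.0)
    return FeatureMap(values, "falff", flags=flags)
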