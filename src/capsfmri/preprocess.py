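"""Per-voxel detrending, band-pass filtering and optional spatial smoothing.

This is the computable residue of the usual resting-state standardization
pipeline once registration is assumed done (synthetic cohorts are generated
directly in atlas space). The fixed wiring is:

* ALFF / fALFF consume **detrended, unfiltered** series (the fALFF
  denominator needs the full spectrum);
* FC, DC and ReHo consume **detrended, band-passed** series;
* ReHo input is never smoothed (the concordance statistic has its own
  smoothing effect); smoothing defaults to off globally.

The band-pass is a frequency-domain boxcar: DFT, zero every bin whose
frequency lies outside ``[low, high]``, inverse DFT. That makes the filter
exactly idempotent and testable bin by bin.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import TimeSeriesVolume

__all__ = [
    "PreprocessConfig",
    "PreparedInputs",
    "detrend_linear",
    "bandpass",
    "smooth_gaussian",
    "prepare_inputs",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass
class PreprocessConfig:
    detrend: str = "linear"  # {"none", "linear"}
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    smooth_fwhm_voxels: float = 0.0

    def __post_init__(self) -> None:
        if self.detrend not in ("none", "linear"):
            raise ValueError(f"detrend must be 'none' or 'linear', got {self.detrend!r}")
        if not 0.0 <= self.band_low_hz < self.band_high_hz:
            raise ValueError(
                f"need 0 <= band_low < band_high, got ({self.band_low_hz}, {self.band_high_hz})"
            )
        if self.smooth_fwhm_voxels < 0:
            raise ValueError("smooth_fwhm_voxels must be >= 0")


def detrend_linear(vol: TimeSeriesVolume) -> TimeSeriesVolume:
    """Remove each voxel's ordinary-least-squares line over time.

    Output series have zero mean and zero linear trend.
    """
    T = vol.n_timepoints
    if T < 3:
        raise ValueError(f"detrending needs >= 3 time points, got {T}")
    t = np.arange(T, dtype=np.float64)
    tc = t - t.mean()
    data = vol.data
    mean = data.mean(axis=3, keepdims=True)
    slope = (data * tc).sum(axis=3, keepdims=True) / (tc * tc).sum()
    out = data - mean - slope * tc
    return TimeSeriesVolume(out, vol.tr_seconds)


def bandpass(
    vol: TimeSeriesVolume, low_hz: float | None = None, high_hz: float | None = None
) -> TimeSeriesVolume:
    """Frequency-domain boxcar band-pass along the time axis.

    Keeps DFT bins with ``low_hz <= f <= high_hz`` (conjugate symmetry is
    preserved by operating on the one-sided real FFT); all other bins,
    including DC, are zeroed.
    """
    low = 0.01 if low_hz is None else float(low_hz)
    high = 0.08 if high_hz is None else float(high_hz)
    nyquist = vol.fs / 2.0
    if not (0.0 <= low < high <= nyquist + 1e-12):
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for fs={vol.fs} Hz (Nyquist {nyquist})"
        )
    T = vol.n_timepoints
    freqs = np.fft.rfftfreq(T, d=vol.tr_seconds)
    keep = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(vol.data, axis=3)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=3)
    return TimeSeriesVolume(out, vol.tr_seconds)


def smooth_gaussian(vol: TimeSeriesVolume, fwhm_voxels: float) -> TimeSeriesVolume:
    """Spatial Gaussian smoothing per time point; ``fwhm = 0`` is the identity."""
    if fwhm_voxels < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_voxels == 0:
        return TimeSeriesVolume(vol.data.copy(), vol.tr_seconds)
    sigma = fwhm_voxels * FWHM_TO_SIGMA
    out = ndimage.gaussian_filter(
        vol.data, sigma=(sigma, sigma, sigma, 0.0), mode="reflect"
    )
    return TimeSeriesVolume(out, vol.tr_seconds)


@dataclasses.dataclass
class PreparedInputs:
    """Preprocessed variants of one subject's volume, one per feature family."""

    spectral: TimeSeriesVolume  # ALFF / fALFF input: detrended only
    filtered: TimeSeriesVolume  # FC / DC input: detrended + band-passed (+ smoothed)
    reho_input: TimeSeriesVolume  # ReHo input: detrended + band-passed, never smoothed


def prepare_inputs(vol: TimeSeriesVolume, cfg: PreprocessConfig | None = None) -> PreparedInputs:
    """Apply the fixed preprocessing wiring to one volume."""
    cfg = cfg or PreprocessConfig()
    base = detrend_linear(vol) if cfg.detrend == "linear" else vol
    filtered = bandpass(base, cfg.band_low_hz, cfg.band_high_hz)
    smoothed = (
        smooth_gaussian(filtered, cfg.smooth_fwhm_voxels)
        if cfg.smooth_fwhm_voxels > 0
        else filtered
    )
    return PreparedInputs(spectral=base, filtered=smoothed, reho_input=filtered)
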