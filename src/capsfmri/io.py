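"""NIfTI volume / atlas I/O and the cohort manifest contract.

Conventions used throughout the package:

* voxel indices are 0-based and the time axis is the **last** axis of a 4D
  array, i.e. ``data[x, y, z, t]``;
* atlas label 0 is background and is excluded from every region statistic;
* volumes containing NaN/Inf are rejected at load time (feature denominators
  are undefined for missing data — fail fast rather than mask).
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesVolume",
    "AtlasParcellation",
    "CohortManifest",
    "VolumeFormatError",
    "AtlasError",
    "ManifestError",
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "read_manifest",
    "write_manifest",
]

MANIFEST_COLUMNS = ("subject_id", "volume_path", "label")


class VolumeFormatError(ValueError):
    """A NIfTI file does not satisfy the 4D time-series contract."""


class AtlasError(ValueError):
    """An atlas parcellation violates its invariants."""


class ManifestError(ValueError):
    """A cohort manifest CSV is malformed."""


@dataclasses.dataclass
class TimeSeriesVolume:
    """A 4D voxel time-series ``data[x, y, z, t]`` with sampling interval.

    Parameters
    ----------
    data
        4D float array, time last.
    tr_seconds
        Repetition time (sampling interval) in seconds; the sampling
        frequency is ``fs = 1 / tr_seconds``.
    """

    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise VolumeFormatError(
                f"expected 4D (x, y, z, t) data, got {self.data.ndim}D"
            )
        if min(self.data.shape[:3]) < 1 or self.data.shape[3] < 2:
            raise VolumeFormatError(f"degenerate volume shape {self.data.shape}")
        if not (self.tr_seconds > 0):
            raise VolumeFormatError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        bad = int(np.count_nonzero(~np.isfinite(self.data)))
        if bad:
            raise VolumeFormatError(f"volume contains {bad} non-finite voxel values")

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.tr_seconds

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclasses.dataclass
class AtlasParcellation:
    """3D integer label volume mapping voxels to brain regions.

    Label 0 is background; the distinct positive labels are the region ids
    and ``n_regions`` is their count (the N of the functional-connectivity
    matrix).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise AtlasError(f"expected a 3D label volume, got {labels.ndim}D")
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = labels.astype(np.int64)
            if not np.array_equal(as_int, labels):
                raise AtlasError("atlas labels must be integers")
            labels = as_int
        if labels.min() < 0:
            raise AtlasError("atlas labels must be non-negative (0 = background)")
        self.labels = labels.astype(np.int64)

    @property
    def region_ids(self) -> np.ndarray:
        """Sorted distinct positive labels."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id


@dataclasses.dataclass
class CohortManifest:
    """Cohort table with columns ``subject_id, volume_path, label``.

    Labels are 0 (control) / 1 (patient). ``volume_path`` entries may be
    relative; they are resolved against ``root`` when set (the directory the
    manifest CSV was read from).
    """

    table: pd.DataFrame
    root: Path | None = None

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in MANIFEST_COLUMNS if c not in t.columns]
        if missing:
            raise ManifestError(f"manifest missing columns {missing}")
        dup = t["subject_id"][t["subject_id"].duplicated()]
        if len(dup):
            raise ManifestError(f"duplicate subject_id {dup.iloc[0]!r}")
        bad = ~t["label"].isin([0, 1])
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1 header + 1-based
            raise ManifestError(
                f"label {t['label'][bad].iloc[0]!r} outside {{0,1}} at line {line}"
            )
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy(dtype=np.int64)

    def volume_path(self, subject_id: str) -> Path:
        row = self.table[self.table["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        p = Path(row["volume_path"].iloc[0])
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p

    def subset(self, subject_ids) -> "CohortManifest":
        keep = self.table[self.table["subject_id"].isin(list(subject_ids))]
        return CohortManifest(keep.copy(), root=self.root)


def read_volume(path: str | os.PathLike, tr_seconds: float | None = None) -> TimeSeriesVolume:
    """Load a 4D NIfTI time series.

    The repetition time is taken from the header's 4th zoom unless
    ``tr_seconds`` overrides it. Volumes with fewer than 8 time points or any
    non-finite voxel are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim < 4:
        raise VolumeFormatError(f"{path}: expected 4D image, got {img.ndim}D")
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim > 4:
        data = data.reshape(data.shape[:4])
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr_seconds > 0:
            raise VolumeFormatError(
                f"{path}: header has no valid TR; pass tr_seconds explicitly"
            )
    vol = TimeSeriesVolume(data, float(tr_seconds))
    if vol.n_timepoints < 8:
        raise VolumeFormatError(
            f"{path}: need >= 8 time points, got {vol.n_timepoints}"
        )
    return vol


def write_volume(vol: TimeSeriesVolume, path: str | os.PathLike) -> Path:
    """Write a 4D NIfTI with the TR recorded in the header zooms."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, vol.tr_seconds))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    return path


def read_atlas(
    path: str | os.PathLike, reference: TimeSeriesVolume | None = None
) -> AtlasParcellation:
    """Load a 3D integer parcellation, optionally checked against a reference grid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise AtlasError(f"{path}: expected a 3D atlas, got {data.ndim}D")
    atlas = AtlasParcellation(data)
    if reference is not None and atlas.labels.shape != reference.spatial_shape:
        raise AtlasError(
            f"{path}: atlas grid {atlas.labels.shape} does not match "
            f"volume grid {reference.spatial_shape}"
        )
    if atlas.n_regions < 2:
        raise AtlasError(f"{path}: need >= 2 regions, found {atlas.n_regions}")
    return atlas


def write_atlas(atlas: AtlasParcellation, path: str | os.PathLike) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), affine=np.eye(4))
    nib.save(img, str(path))
    return path


def read_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read a cohort manifest CSV with header ``subject_id,volume_path,label``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        t = pd.read_csv(path, dtype={"subject_id": str, "volume_path": str})
    except Exception as exc:  # noqa: BLE001 - surface the CSV parser message
        raise ManifestError(f"{path}: unreadable manifest ({exc})") from exc
    if list(t.columns) != list(MANIFEST_COLUMNS):
        raise ManifestError(
            f"{path}: header must be {','.join(MANIFEST_COLUMNS)}, got {list(t.columns)}"
        )
    labels = pd.to_numeric(t["label"], errors="coerce")
    bad = ~labels.isin([0, 1])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ManifestError(f"{path}: invalid label at line {line}")
    t["label"] = labels.astype(np.int64)
    return CohortManifest(t, root=path.parent)


def write_manifest(manifest: CohortManifest, path: str | os.PathLike) -> Path:
    path = Path(path)
    manifest.table.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))
    return path
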