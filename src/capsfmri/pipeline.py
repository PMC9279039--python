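"""Cohort-level plumbing: feature extraction over a manifest and
manifest-driven training of the capsule classifier.

Feature maps are written as 3D NIfTI files named ``{subject_id}_{feature}.nii.gz``
next to a per-subject feature table CSV (region means of each map plus the
lower-triangle FC vector). The classifier consumes per-subject feature maps
reduced to mid-slices: each 3D map is z-scored within subject (switchable),
then its axial mid-slice (or the three orthogonal mid-slices) is stacked as
input channels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .capsnet.model import CapsNetClassifier, CapsNetConfig, Prediction
from .connectivity import fc_features, fc_matrix, region_means
from .features import FeatureMap, SpectrumConfig, alff, degree_centrality, falff, reho
from .io import AtlasParcellation, CohortManifest, read_volume
from .preprocess import PreprocessConfig, prepare_inputs

__all__ = [
    "ExtractionConfig",
    "extract_subject_features",
    "extract_features",
    "load_feature_map",
    "stack_feature_input",
    "build_dataset",
    "train",
    "predict",
]

VOXEL_FEATURES = ("alff", "falff", "reho", "dc")


@dataclasses.dataclass
class ExtractionConfig:
    features: tuple[str, ...] = ("alff", "falff", "reho", "dc")
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    spectrum: SpectrumConfig = dataclasses.field(default_factory=SpectrumConfig)
    dc_threshold: float = 0.25
    dc_absolute: bool = False
    reho_neighborhood: int = 27
    include_fc: bool = False  # add the FC lower-triangle vector to the table

    def __post_init__(self) -> None:
        bad = set(self.features) - set(VOXEL_FEATURES)
        if bad:
            raise ValueError(f"unknown features {sorted(bad)}; choose from {VOXEL_FEATURES}")


def extract_subject_features(
    vol, cfg: ExtractionConfig | None = None
) -> dict[str, FeatureMap]:
    """Compute the requested per-voxel feature maps for one volume.

    Applies the fixed preprocessing wiring: ALFF/fALFF see the detrended
    unfiltered series, DC the band-passed (optionally smoothed) series, and
    ReHo the band-passed unsmoothed series.
    """
    cfg = cfg or ExtractionConfig()
    prepared = prepare_inputs(vol, cfg.preprocess)
    maps: dict[str, FeatureMap] = {}
    for name in cfg.features:
        if name == "alff":
            maps[name] = alff(prepared.spectral, cfg.spectrum)
        elif name == "falff":
            maps[name] = falff(prepared.spectral, cfg.spectrum)
        elif name == "dc":
            maps[name] = degree_centrality(
                prepared.filtered, threshold=cfg.dc_threshold, absolute=cfg.dc_absolute
            )
        elif name == "reho":
            maps[name] = reho(prepared.reho_input, neighborhood=cfg.reho_neighborhood)
    return maps


def _save_map(fmap: FeatureMap, path: Path) -> None:
    img = nib.Nifti1Image(fmap.values.astype(np.float64), affine=np.eye(4))
    nib.save(img, str(path))


def load_feature_map(features_dir: Path, subject_id: str, feature: str) -> np.ndarray:
    path = Path(features_dir) / f"{subject_id}_{feature}.nii.gz"
    if not path.exists():
        raise FileNotFoundError(
            f"missing {feature} map for subject {subject_id}: {path}"
        )
    return np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)


def extract_features(
    manifest: CohortManifest,
    atlas: AtlasParcellation,
    out_dir: str | Path,
    cfg: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Extract feature maps for every manifest subject and write them to disk.

    Returns (and writes as ``features.csv``) the per-subject feature table:
    region means of each voxel map and, when ``include_fc`` is set, the FC
    lower-triangle entries.
    """
    cfg = cfg or ExtractionConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    region_ids = atlas.region_ids
    for sid in manifest.subject_ids:
        vol = read_volume(manifest.volume_path(sid))
        if atlas.labels.shape != vol.spatial_shape:
            raise ValueError(f"subject {sid}: volume grid does not match atlas")
        maps = extract_subject_features(vol, cfg)
        row: dict = {"subject_id": sid}
        for name, fmap in maps.items():
            fmap.subject_id = sid
            _save_map(fmap, out_dir / f"{sid}_{name}.nii.gz")
            for rid in region_ids:
                row[f"{name}_region{rid}"] = float(
                    fmap.values[atlas.labels == rid].mean()
                )
        if cfg.include_fc:
            prepared = prepare_inputs(vol, cfg.preprocess)
            vec = fc_features(fc_matrix(region_means(prepared.filtered, atlas)))
            for k, v in enumerate(vec):
                row[f"fc_{k}"] = float(v)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "features.csv", index=False)
    return table


def stack_feature_input(
    maps: list[np.ndarray], zscore: bool = True, slices: str = "axial"
) -> np.ndarray:
    """Reduce a subject's 3D feature maps to stacked 2D channels.

    Each map is z-scored within subject (unless disabled, or the map is
    constant), then reduced to its axial mid-slice ``[:, :, Z//2]`` or to the
    three orthogonal mid-slices (requires a cubic grid).
    """
    channels = []
    for m in maps:
        m = np.asarray(m, dtype=np.float64)
        if m.ndim != 3:
            raise ValueError("feature maps must be 3D")
        if zscore:
            sd = m.std()
            m = (m - m.mean()) / sd if sd > 0 else m - m.mean()
        X, Y, Z = m.shape
        if slices == "axial":
            channels.append(m[:, :, Z // 2])
        elif slices == "triplanar":
            if not (X == Y == Z):
                raise ValueError("triplanar slicing requires a cubic grid")
            channels.extend([m[X // 2, :, :], m[:, Y // 2, :], m[:, :, Z // 2]])
        else:
            raise ValueError(f"unknown slice mode {slices!r}")
    return np.stack(channels, axis=0)


def build_dataset(
    manifest: CohortManifest,
    feature_set: list[str],
    features_dir: str | Path,
    zscore: bool = True,
    slices: str = "axial",
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (X, y) classifier inputs for every manifest subject."""
    X, y = [], []
    for sid, label in zip(manifest.subject_ids, manifest.labels):
        maps = [load_feature_map(features_dir, sid, f) for f in feature_set]
        X.append(stack_feature_input(maps, zscore=zscore, slices=slices))
        y.append(label)
    return np.stack(X, axis=0), np.asarray(y, dtype=np.int64)


def train(
    manifest: CohortManifest,
    feature_set: list[str],
    cfg: CapsNetConfig,
    features_dir: str | Path,
) -> CapsNetClassifier:
    """Train a capsule classifier from a manifest and precomputed feature maps."""
    labels = manifest.labels
    if np.unique(labels).size < 2:
        raise ValueError("manifest contains a single class; training needs both")
    X, y = build_dataset(
        manifest, feature_set, features_dir, zscore=cfg.zscore, slices=cfg.slices
    )
    return CapsNetClassifier(cfg).fit(X, y)


def predict(
    model: CapsNetClassifier, maps: list[np.ndarray]
) -> Prediction:
    """Predict one subject from their raw 3D feature maps."""
    x = stack_feature_input(maps, zscore=model.config.zscore, slices=model.config.slices)
    return model.predict_one(x)
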