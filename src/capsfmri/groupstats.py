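"""Voxelwise two-sample group comparison with cluster reporting.

Computes a per-voxel two-sample t statistic (pooled variance by default,
Welch optional) between two groups of per-subject scalar maps, thresholds
it, extracts connected suprathreshold components split by sign, and reports
each surviving cluster's voxel count, peak T, peak Z (the standard-normal
quantile matching the t's two-sided tail probability, signed like t) and
peak coordinates — the classic cluster-table layout of voxelwise
neuroimaging group studies. No multiple-comparison correction is applied by
default; an optional FDR step over voxel p-values is provided.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "TMap",
    "ClusterRecord",
    "voxelwise_t",
    "t_to_z",
    "extract_clusters",
    "cluster_table",
    "fdr_mask",
]


@dataclasses.dataclass
class TMap:
    """Voxelwise t statistics with their degrees of freedom."""

    t: np.ndarray
    df: float
    flags: np.ndarray  # voxels with zero pooled variance (t set to 0 there)


@dataclasses.dataclass
class ClusterRecord:
    cluster_id: int
    voxel_count: int
    peak_T: float
    peak_Z: float
    peak_coordinates: tuple[int, int, int]
    sign: str  # {"increase", "decrease"}: sign of group_a - group_b at the peak
    voxels: np.ndarray | None = None  # (k, 3) coordinates of the component


def voxelwise_t(
    group_a: np.ndarray, group_b: np.ndarray, equal_var: bool = True
) -> TMap:
    """Two-sample t statistic per voxel, oriented as ``group_a - group_b``.

    ``group_a``/``group_b`` are stacked (n_subjects, x, y, z) arrays. Voxels
    with zero variance in both groups are flagged and set to t = 0.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.ndim != 4 or b.ndim != 4:
        raise ValueError("groups must be (n_subjects, x, y, z)")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError(f"grid mismatch: {a.shape[1:]} vs {b.shape[1:]}")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 subjects")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    if equal_var:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        denom = np.sqrt(va / na + vb / nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            df_map = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        df = float(np.nanmedian(df_map)) if np.isfinite(df_map).any() else float(na + nb - 2)
    flags = denom == 0.0
    t = np.zeros_like(ma)
    np.divide(ma - mb, denom, out=t, where=~flags)
    return TMap(t=t, df=df, flags=flags)


def t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Map t to the standard-normal quantile of its two-sided tail, keeping sign.

    Monotone in t, with z(0) = 0; extreme t values are clamped to the finite
    quantile range.
    """
    t = np.asarray(t, dtype=np.float64)
    p_half = stats.t.sf(np.abs(t), df)
    z = stats.norm.isf(np.clip(p_half, 1e-300, None))
    return np.sign(t) * np.minimum(z, stats.norm.isf(1e-300))


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def extract_clusters(
    tmap: TMap,
    t_threshold: float,
    min_extent: int = 1,
    connectivity: int = 26,
) -> list[ClusterRecord]:
    """Connected suprathreshold clusters of |t| > threshold, split by sign.

    Components smaller than ``min_extent`` voxels are dropped; the peak is
    the max-|t| voxel of the component. Records are sorted by voxel count
    (largest first), then by |peak T|.
    """
    if not (np.isfinite(t_threshold) and t_threshold > 0):
        raise ValueError("t_threshold must be a finite positive number")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    records: list[ClusterRecord] = []
    for sign, mask in (
        ("increase", tmap.t > t_threshold),
        ("decrease", tmap.t < -t_threshold),
    ):
        labeled, n = ndimage.label(mask, structure=structure)
        for comp in range(1, n + 1):
            voxels = np.argwhere(labeled == comp)
            if voxels.shape[0] < min_extent:
                continue
            tvals = tmap.t[tuple(voxels.T)]
            peak_i = int(np.abs(tvals).argmax())
            peak = tuple(int(c) for c in voxels[peak_i])
            peak_t = float(tvals[peak_i])
            records.append(
                ClusterRecord(
                    cluster_id=0,
                    voxel_count=int(voxels.shape[0]),
                    peak_T=peak_t,
                    peak_Z=float(t_to_z(np.array(peak_t), tmap.df)),
                    peak_coordinates=peak,
                    sign=sign,
                    voxels=voxels,
                )
            )
    records.sort(key=lambda r: (-r.voxel_count, -abs(r.peak_T)))
    for i, rec in enumerate(records):
        rec.cluster_id = i + 1
    return records


def cluster_table(records: list[ClusterRecord], df: float | None = None) -> pd.DataFrame:
    """Cluster records as a table (voxel count, Z, T, p per cluster)."""
    rows = []
    for r in records:
        p = float(2.0 * stats.t.sf(abs(r.peak_T), df)) if df is not None else np.nan
        rows.append(
            {
                "cluster_id": r.cluster_id,
                "voxel_count": r.voxel_count,
                "peak_x": r.peak_coordinates[0],
                "peak_y": r.peak_coordinates[1],
                "peak_z": r.peak_coordinates[2],
                "Z": r.peak_Z,
                "T": r.peak_T,
                "p": p,
                "sign": r.sign,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "voxel_count",
            "peak_x",
            "peak_y",
            "peak_z",
            "Z",
            "T",
            "p",
            "sign",
        ],
    )


def fdr_mask(tmap: TMap, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg FDR mask over voxelwise two-sided p-values."""
    p = 2.0 * stats.t.sf(np.abs(tmap.t), tmap.df)
    p_adj = stats.false_discovery_control(p.ravel(), method="bh")
    return (p_adj <= q).reshape(tmap.t.shape)
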