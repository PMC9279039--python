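"""Synthetic two-class resting-state cohorts in atlas space.

The generator emulates a depression-vs-control cohort whose classes differ
in exactly the three signal channels the downstream features detect:

* **amplitude** — every region carries a low-frequency oscillation (sum of
  sinusoids with frequencies drawn uniformly in 0.01–0.08 Hz); in affected
  regions of patients its amplitude is multiplied by ``1 + effect_alff``
  (ALFF / fALFF channel);
* **coupling** — affected regions of patients share a common oscillation
  component mixed in variance-preservingly with weight ``effect_fc``, so the
  induced inter-region correlation equals ``effect_fc`` (FC / DC channel);
* **local synchrony** — within affected regions of patients a variance share
  ``effect_reho`` of each voxel's noise is a region-shared component
  (ReHo channel).

Everything is deterministic given ``(config.seed, subject_seed, label)``.
The model is deliberately simple — Gaussian white noise plus sinusoids, no
hemodynamics, motion or physiological noise — because the features under
test are spectral and correlational and need controllable ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .io import (
    AtlasParcellation,
    CohortManifest,
    TimeSeriesVolume,
    write_atlas,
    write_manifest,
    write_volume,
)
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "make_block_atlas",
    "simulate_subject",
    "simulate_cohort",
]

# Per-region oscillation: N_OSC sinusoids of amplitude OSC_AMPLITUDE each.
# With unit noise and the default 0.01-0.08 Hz band this puts baseline
# within-region voxel correlations around 0.4-0.5 after band-passing.
N_OSC = 3
OSC_AMPLITUDE = 0.4
OSC_BAND = (0.01, 0.08)


@dataclasses.dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults follow the 70-patient / 30-control scale of the clinical cohort
    the generator stands in for, on a 12x12x12 grid of 8 block regions with
    TR = 2 s and 128 time points.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_regions: int = 8
    n_timepoints: int = 128
    tr_seconds: float = 2.0
    n_patients: int = 70
    n_controls: int = 30
    effect_alff: float = 0.0
    effect_fc: float = 0.0
    effect_reho: float = 0.0
    affected_regions: tuple[int, ...] = (1, 2)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        self.affected_regions = tuple(int(r) for r in self.affected_regions)
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValueError(f"invalid grid_shape {self.grid_shape}")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_timepoints < 16:
            raise ValueError("n_timepoints must be >= 16")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be > 0")
        if not self.affected_regions:
            raise ValueError("at least one affected region is required")
        for e in (self.effect_alff, self.effect_fc, self.effect_reho):
            if not np.isfinite(e):
                raise ValueError("effect sizes must be finite")
        if self.effect_alff < 0:
            raise ValueError("effect_alff must be >= 0")
        if not -1.0 <= self.effect_fc <= 1.0:
            raise ValueError("effect_fc must lie in [-1, 1]")
        if not 0.0 <= self.effect_reho <= 1.0:
            raise ValueError("effect_reho must lie in [0, 1]")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        bad = set(self.affected_regions) - set(range(1, self.n_regions + 1))
        if bad:
            raise ValueError(f"affected_regions {sorted(bad)} outside 1..n_regions")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["affected_regions"] = list(self.affected_regions)
        return d


@dataclasses.dataclass
class SimulatedCohort:
    """A generated cohort: manifest + atlas + per-subject ground truth."""

    manifest: CohortManifest
    atlas: AtlasParcellation
    ground_truth: dict
    out_dir: Path
    atlas_path: Path
    manifest_path: Path


def _factor_triples(n: int):
    for a in range(1, n + 1):
        if n % a:
            continue
        m = n // a
        for b in range(1, m + 1):
            if m % b:
                continue
            yield a, b, m // b


def make_block_atlas(
    grid_shape: tuple[int, int, int], n_regions: int, seed: int = 0
) -> AtlasParcellation:
    """Partition a grid into ``n_regions`` contiguous rectangular blocks.

    The factorization of ``n_regions`` into per-axis split counts is chosen
    to keep blocks as close to cubic as possible (a 4x4x4 grid with 8
    regions yields the eight 2x2x2 octants). Labels run 1..n_regions in
    x-major, z-minor raster order of the blocks. Deterministic; ``seed`` is
    accepted for interface symmetry with the other generators.
    """
    gx, gy, gz = grid_shape
    n_voxels = gx * gy * gz
    if n_regions > n_voxels:
        raise ValueError(f"n_regions={n_regions} exceeds voxel count {n_voxels}")
    best = None
    for a, b, c in _factor_triples(n_regions):
        if a > gx or b > gy or c > gz:
            continue
        sides = (gx / a, gy / b, gz / c)
        cost = max(sides) / min(sides)
        if best is None or cost < best[0]:
            best = (cost, (a, b, c))
    labels = np.zeros(grid_shape, dtype=np.int64)
    if best is not None:
        a, b, c = best[1]
        xs = np.array_split(np.arange(gx), a)
        ys = np.array_split(np.arange(gy), b)
        zs = np.array_split(np.arange(gz), c)
        lab = 1
        for xi in xs:
            for yi in ys:
                for zi in zs:
                    labels[np.ix_(xi, yi, zi)] = lab
                    lab += 1
    else:
        # n_regions has no axis-aligned factorization inside the grid
        # (e.g. a large prime): fall back to equal runs in raster order.
        flat = np.repeat(
            np.arange(1, n_regions + 1),
            np.diff(np.linspace(0, n_voxels, n_regions + 1).astype(int)),
        )
        labels = flat.reshape(grid_shape)
    return AtlasParcellation(labels)


def _oscillation(rng: np.random.Generator, t: np.ndarray) -> np.ndarray:
    """Sum of N_OSC random sinusoids inside the low-frequency band."""
    freqs = rng.uniform(*OSC_BAND, size=N_OSC)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=N_OSC)
    return (OSC_AMPLITUDE * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None])).sum(
        axis=0
    )


def simulate_subject(
    config: SimulationConfig,
    atlas: AtlasParcellation,
    label: int,
    subject_seed: int,
) -> TimeSeriesVolume:
    """Simulate one subject's 4D volume on the atlas grid.

    ``label`` 1 (patient) switches on the configured effects in the affected
    regions; label 0 (control) subjects carry baseline signal only. The same
    ``(config, label, subject_seed)`` always yields the same volume.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    rng = np.random.default_rng([config.seed, int(subject_seed), int(label)])
    t = np.arange(config.n_timepoints) * config.tr_seconds
    shape = atlas.labels.shape
    region_ids = atlas.region_ids
    affected = set(config.affected_regions)
    is_patient = label == 1

    # region oscillations (always drawn, so the RNG stream does not depend
    # on the effect sizes and a null cohort is the exact zero-effect limit)
    own = {rid: _oscillation(rng, t) for rid in region_ids}
    shared_osc = _oscillation(rng, t)

    osc = {}
    w = config.effect_fc
    for rid in region_ids:
        x = own[rid]
        if is_patient and rid in affected and w != 0.0:
            x = np.sqrt(1.0 - abs(w)) * x + np.sign(w) * np.sqrt(abs(w)) * shared_osc
        if is_patient and rid in affected:
            x = (1.0 + config.effect_alff) * x
        osc[rid] = x

    data = rng.normal(0.0, config.noise_sd, size=shape + (config.n_timepoints,))
    shared_noise = {
        rid: rng.normal(0.0, config.noise_sd, size=config.n_timepoints)
        for rid in region_ids
    }
    e = config.effect_reho
    for rid in region_ids:
        mask = atlas.labels == rid
        if is_patient and rid in affected and e > 0.0:
            data[mask] = np.sqrt(1.0 - e) * data[mask] + np.sqrt(e) * shared_noise[rid]
        data[mask] += osc[rid]
    return TimeSeriesVolume(data, config.tr_seconds)


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Write a full cohort (volumes, atlas, manifest CSV, ground-truth JSON).

    Subject ids are ``sub-p###`` (patients, label 1) then ``sub-c###``
    (controls, label 0); regeneration with the same config is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    atlas = make_block_atlas(config.grid_shape, config.n_regions, config.seed)
    atlas_path = write_atlas(atlas, out_dir / "atlas.nii.gz")

    rows = []
    truth_subjects = []
    subjects = [("sub-p%03d" % (i + 1), 1, i) for i in range(config.n_patients)]
    subjects += [("sub-c%03d" % (i + 1), 0, i) for i in range(config.n_controls)]
    for sid, label, sseed in subjects:
        vol = simulate_subject(config, atlas, label, sseed)
        fname = f"{sid}.nii.gz"
        write_volume(vol, out_dir / fname)
        rows.append({"subject_id": sid, "volume_path": fname, "label": label})
        truth_subjects.append(
            {
                "subject_id": sid,
                "label": label,
                "subject_seed": sseed,
                "effects_applied": bool(label == 1),
            }
        )

    manifest = CohortManifest(pd.DataFrame(rows), root=out_dir)
    manifest_path = write_manifest(manifest, out_dir / "manifest.csv")
    ground_truth = {
        "config": config.to_dict(),
        "affected_regions": list(config.affected_regions),
        "subjects": truth_subjects,
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return SimulatedCohort(
        manifest=manifest,
        atlas=atlas,
        ground_truth=ground_truth,
        out_dir=out_dir,
        atlas_path=atlas_path,
        manifest_path=manifest_path,
    )
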