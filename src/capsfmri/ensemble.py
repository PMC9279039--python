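"""Multi-feature ensemble fusion and classification metrics.

Per-feature capsule models each emit a vector of class-capsule lengths;
capsule lengths do not sum to one, so each member's score vector is first
normalized to a unit sum and the fused vector is the weighted average of the
normalized members (uniform weights by default). The reported metrics are

* ``correct_rate`` — (TP + TN) / n,
* ``recall`` — TP / (TP + FN),
* ``precision`` — TP / (TP + FP),

with class 1 (patient) as the positive class. Undefined ratios are reported
as NaN with a warning, never silently 0.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .capsnet.model import CapsNetClassifier, CapsNetConfig
from .io import CohortManifest
from .pipeline import ExtractionConfig, build_dataset, extract_features

__all__ = [
    "EnsembleConfig",
    "EvalReport",
    "normalize_scores",
    "ensemble_predict",
    "fuse_scores",
    "evaluate",
    "stratified_split",
    "run_experiment",
    "ExperimentResult",
]


@dataclasses.dataclass
class EnsembleConfig:
    """Member models (feature name -> model path) and fusion weights."""

    members: list[tuple[str, str]]
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("ensemble needs at least one member")
        if len(self.members) < 2:
            warnings.warn("ensemble with a single member is degenerate", stacklevel=2)
        if self.weights is None:
            self.weights = [1.0 / len(self.members)] * len(self.members)
        w = np.asarray(self.weights, dtype=np.float64)
        if w.size != len(self.members):
            raise ValueError("weights length must equal members length")
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        self.weights = list(map(float, w))


@dataclasses.dataclass
class EvalReport:
    """Confusion counts, the three headline metrics and per-subject predictions."""

    tp: int
    fp: int
    fn: int
    tn: int
    correct_rate: float
    recall: float
    precision: float
    predictions: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def summary(self) -> str:
        def fmt(x):
            return "undefined" if np.isnan(x) else f"{100 * x:.2f}%"

        lines = [
            "classification report",
            "---------------------",
            f"n = {self.n}   TP={self.tp} FP={self.fp} FN={self.fn} TN={self.tn}",
            f"correct rate : {fmt(self.correct_rate)}",
            f"recall       : {fmt(self.recall)}",
            f"precision    : {fmt(self.precision)}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "correct_rate": self.correct_rate,
            "recall": self.recall,
            "precision": self.precision,
        }


def normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Normalize score vectors to unit sum (uniform when the sum is zero)."""
    scores = np.asarray(scores, dtype=np.float64)
    s = scores.sum(axis=-1, keepdims=True)
    out = np.full_like(scores, 1.0 / scores.shape[-1])
    np.divide(scores, s, out=out, where=s > 0)
    return out


def fuse_scores(member_scores: list[np.ndarray], weights=None) -> np.ndarray:
    """Weighted average of per-member normalized score vectors."""
    if not member_scores:
        raise ValueError("no member scores")
    if weights is None:
        weights = [1.0 / len(member_scores)] * len(member_scores)
    if len(weights) != len(member_scores):
        raise ValueError("weights length must equal number of members")
    fused = None
    for w, s in zip(weights, member_scores):
        contrib = w * normalize_scores(s)
        fused = contrib if fused is None else fused + contrib
    return fused


def ensemble_predict(member_scores: list[np.ndarray], weights=None) -> np.ndarray:
    """Fused class decision; argmax ties break toward the lower class index."""
    return fuse_scores(member_scores, weights).argmax(axis=-1)


def evaluate(predictions: np.ndarray, labels: np.ndarray, subject_ids=None) -> EvalReport:
    """Confusion counts and the three metrics for binary predictions."""
    predictions = np.asarray(predictions, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be in {0, 1}")
    tp = int(((predictions == 1) & (labels == 1)).sum())
    fp = int(((predictions == 1) & (labels == 0)).sum())
    fn = int(((predictions == 0) & (labels == 1)).sum())
    tn = int(((predictions == 0) & (labels == 0)).sum())
    n = tp + fp + fn + tn
    correct = (tp + tn) / n if n else np.nan
    if tp + fn:
        recall = tp / (tp + fn)
    else:
        warnings.warn("no positive labels: recall undefined", stacklevel=2)
        recall = np.nan
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        warnings.warn("no positive predictions: precision undefined", stacklevel=2)
        precision = np.nan
    table = None
    if subject_ids is not None:
        table = pd.DataFrame(
            {"subject_id": list(subject_ids), "label": labels, "prediction": predictions}
        )
    return EvalReport(tp, fp, fn, tn, correct, recall, precision, predictions=table)


def stratified_split(
    labels: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Index split preserving class proportions within one subject."""
    labels = np.asarray(labels)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * idx.size)))
        test_idx.append(idx[:n_test])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(labels.size), test)
    return train, test


@dataclasses.dataclass
class ExperimentResult:
    member_reports: dict[str, EvalReport]
    ensemble_report: EvalReport
    models: dict[str, CapsNetClassifier]
    train_ids: list[str]
    test_ids: list[str]

    def summary(self) -> str:
        lines = ["held-out evaluation", "==================="]
        for name, rep in self.member_reports.items():
            lines += [f"[{name}]", rep.summary(), ""]
        lines += ["[ensemble]", self.ensemble_report.summary()]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "members": {k: r.to_dict() for k, r in self.member_reports.items()},
            "ensemble": self.ensemble_report.to_dict(),
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
        }


def run_experiment(
    manifest: CohortManifest,
    atlas,
    features: list[str],
    caps_cfg: CapsNetConfig,
    work_dir: str | Path,
    split_seed: int = 0,
    test_fraction: float = 0.2,
    weights=None,
    extraction: ExtractionConfig | None = None,
    report_path: str | Path | None = None,
) -> ExperimentResult:
    """Train one capsule model per feature and evaluate members + ensemble.

    A single stratified held-out split (default 20%) is drawn with
    ``split_seed``; every member is trained on the same training subjects and
    scored on the same held-out subjects, then fused by weighted averaging.
    """
    labels = manifest.labels
    if np.unique(labels).size < 2:
        raise ValueError("cohort must contain both classes")
    work_dir = Path(work_dir)
    extraction = extraction or ExtractionConfig(features=tuple(features))
    features_dir = work_dir / "feature_maps"
    extract_features(manifest, atlas, features_dir, extraction)

    train_idx, test_idx = stratified_split(labels, test_fraction, split_seed)
    ids = np.asarray(manifest.subject_ids)
    member_reports: dict[str, EvalReport] = {}
    models: dict[str, CapsNetClassifier] = {}
    member_scores = []
    for feat in features:
        X, y = build_dataset(
            manifest, [feat], features_dir, zscore=caps_cfg.zscore, slices=caps_cfg.slices
        )
        cfg = dataclasses.replace(caps_cfg)
        model = CapsNetClassifier(cfg).fit(X[train_idx], y[train_idx])
        scores = model.predict_scores(X[test_idx])
        member_scores.append(scores)
        member_reports[feat] = evaluate(
            scores.argmax(axis=1), y[test_idx], subject_ids=ids[test_idx]
        )
        models[feat] = model
    fused = ensemble_predict(member_scores, weights)
    ensemble_report = evaluate(fused, labels[test_idx], subject_ids=ids[test_idx])
    result = ExperimentResult(
        member_reports=member_reports,
        ensemble_report=ensemble_report,
        models=models,
        train_ids=list(ids[train_idx]),
        test_ids=list(ids[test_idx]),
    )
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result
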