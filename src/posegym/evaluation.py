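"""Evaluation machinery: confusion matrices, classification metrics,
sequence-level stratified k-fold cross-validation, and the window-accuracy
versus window-length curve used to pick the ensemble's frame count.

The evaluation unit is the window decision: every K-frame window of a test
sequence contributes one prediction, scored against the sequence's label.
Aggregate precision/recall/F1 are reported both macro-averaged (headline)
and support-weighted.  A class never predicted has undefined precision;
it is reported as 0 and flagged, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .landmarks import (
    EXERCISE_CLASS_NAMES,
    ExerciseClass,
    PoseSequence,
    read_manifest,
    read_sequence,
)
from .features import DEFAULT_ANGLES, AngleSpec, extract_sequence_features, feature_matrix
from .cnn import ModelConfig, TrainedModel, build_model, predict_batch, train
from .ensemble import EnsembleConfig, classify_stream

__all__ = [
    "EvalReport",
    "compute_metrics",
    "confusion_from_decisions",
    "stratified_kfold_evaluate",
    "accuracy_vs_frames",
    "export_report",
]

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    """Metrics derived from one confusion matrix (rows = true class,
    columns = predicted class)."""

    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    n_decisions: int
    undefined_precision: list[int] = field(default_factory=list)
    undefined_recall: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        for k in ("precision", "recall", "f1"):
            d[k] = getattr(self, k).tolist()
        return d

    def to_markdown(self, class_names: Sequence[str] = EXERCISE_CLASS_NAMES) -> str:
        lines = [
            f"Decisions: {self.n_decisions}   Accuracy: {self.accuracy:.4f}",
            "",
            "| class | precision | recall | F1 |",
            "|---|---|---|---|",
        ]
        for i in range(self.confusion.shape[0]):
            name = class_names[i] if i < len(class_names) else str(i)
            flag = " *" if i in self.undefined_precision else ""
            lines.append(
                f"| {name}{flag} | {self.precision[i]:.4f} | "
                f"{self.recall[i]:.4f} | {self.f1[i]:.4f} |"
            )
        lines += [
            f"| **macro** | {self.macro_precision:.4f} | "
            f"{self.macro_recall:.4f} | {self.macro_f1:.4f} |",
        ]
        if self.undefined_precision:
            lines.append("")
            lines.append("`*` precision undefined (class never predicted), reported as 0.")
        return "\n".join(lines)


def compute_metrics(cm: np.ndarray) -> EvalReport:
    """Accuracy, per-class and averaged precision/recall/F1 from a square
    confusion matrix of counts."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("confusion matrix is empty (no decisions)")

    diag = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    undefined_p = np.flatnonzero(col == 0)
    undefined_r = np.flatnonzero(row == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)

    # macro: unweighted mean over classes with defined values
    def _macro(values: np.ndarray, undefined: np.ndarray) -> float:
        mask = np.ones(len(values), dtype=bool)
        mask[undefined] = False
        return float(values[mask].mean()) if mask.any() else 0.0

    support = row / total
    return EvalReport(
        confusion=cm.astype(int),
        accuracy=float(diag.sum() / total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=_macro(precision, undefined_p),
        macro_recall=_macro(recall, undefined_r),
        macro_f1=_macro(f1, np.union1d(undefined_p, undefined_r)),
        weighted_precision=float((support * precision).sum()),
        weighted_recall=float((support * recall).sum()),
        weighted_f1=float((support * f1).sum()),
        n_decisions=total,
        undefined_precision=undefined_p.tolist(),
        undefined_recall=undefined_r.tolist(),
    )


def confusion_from_decisions(
    pairs: Sequence[tuple[int, int]], n_classes: int = len(EXERCISE_CLASS_NAMES)
) -> np.ndarray:
    """Count (true index, predicted index) pairs into an n x n matrix."""
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in pairs:
        cm[t, p] += 1
    return cm


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _load_labelled_sequences(
    manifest_path: str | Path,
) -> list[PoseSequence]:
    seqs = []
    for path, cls, sid in read_manifest(manifest_path):
        seq = read_sequence(path)
        seq.label = cls
        seq.sequence_id = sid
        seqs.append(seq)
    return seqs


def _stratified_folds(
    labels: Sequence[int], k: int, seed: int
) -> list[np.ndarray]:
    """Assign sequence indices to k folds, stratified by class: each
    class's sequences are shuffled then dealt round-robin."""
    labels = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    rng = np.random.default_rng(seed)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class index {cls} has {idx.size} sequences, fewer than k={k}"
            )
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def _sequence_frames(
    seqs: Sequence[PoseSequence],
    specs: Sequence[AngleSpec],
    standardize: bool,
) -> list[tuple[np.ndarray, int]]:
    out = []
    for seq in seqs:
        mat = feature_matrix(
            extract_sequence_features(seq, specs, standardize=standardize)
        )
        out.extend((mat[i], seq.label.index) for i in range(mat.shape[0]))
    return out


def stratified_kfold_evaluate(
    manifest_path: str | Path,
    model_config: ModelConfig = ModelConfig(),
    ensemble_config: EnsembleConfig = EnsembleConfig(),
    k: int = 5,
    seed: int = 0,
    *,
    epochs: Optional[int] = None,
    specs: Sequence[AngleSpec] = DEFAULT_ANGLES,
    standardize: bool = False,
) -> tuple[list[EvalReport], EvalReport]:
    """Sequence-level stratified k-fold cross-validation.

    Folds are stratified by class at the sequence level (frames of one
    sequence never straddle train and test).  Each fold trains a fresh
    model on the other folds' frames and scores window decisions on its
    own sequences.  Returns per-fold reports and a pooled report whose
    confusion matrix is the sum over folds.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    seqs = _load_labelled_sequences(manifest_path)
    labels = [s.label.index for s in seqs]
    folds = _stratified_folds(labels, k, seed)

    n_classes = model_config.n_classes
    fold_reports: list[EvalReport] = []
    pooled = np.zeros((n_classes, n_classes), dtype=int)
    for fold_i, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train_seqs = [s for i, s in enumerate(seqs) if i not in test_set]
        test_seqs = [seqs[i] for i in test_idx]
        model = build_model(model_config)
        train(
            model,
            _sequence_frames(train_seqs, specs, standardize),
            epochs=epochs,
            seed=seed + fold_i,
        )
        pairs = []
        for seq in test_seqs:
            for dec in classify_stream(
                model, seq, ensemble_config, specs=specs, standardize=standardize
            ):
                pairs.append((seq.label.index, dec.predicted.index))
        cm = confusion_from_decisions(pairs, n_classes)
        fold_reports.append(compute_metrics(cm))
        pooled += cm
    return fold_reports, compute_metrics(pooled)


def accuracy_vs_frames(
    model: TrainedModel,
    test_sequences: Sequence[PoseSequence],
    frame_counts: Sequence[int] = (1, 5, 10, 15, 20, 30, 45, 60),
    *,
    specs: Sequence[AngleSpec] = DEFAULT_ANGLES,
    standardize: bool = False,
) -> pd.DataFrame:
    """Window accuracy as a function of the window length K.

    For each K (deduplicated, ascending) every test sequence of length
    >= K contributes its non-overlapping K-frame window decisions;
    accuracy is the fraction of correct decisions.  K values longer than
    every sequence are skipped with a warning.  Returns a DataFrame with
    columns ``K`` and ``accuracy``.
    """
    # per-frame probabilities computed once per sequence, reused per K
    cached: list[tuple[int, np.ndarray]] = []
    for seq in test_sequences:
        if seq.label is None:
            raise ValueError(f"sequence {seq.sequence_id!r} has no label")
        X = feature_matrix(
            extract_sequence_features(seq, specs, standardize=standardize)
        )
        cached.append((seq.label.index, predict_batch(model, X)))

    rows = []
    for K in sorted(set(int(k) for k in frame_counts)):
        correct = 0
        n = 0
        for true_idx, probs in cached:
            if probs.shape[0] < K:
                continue
            for start in range(0, probs.shape[0] - K + 1, K):
                scores = probs[start : start + K].sum(axis=0)
                correct += int(np.argmax(scores) == true_idx)
                n += 1
        if n == 0:
            logger.warning("window K=%d exceeds every test sequence; skipped", K)
            continue
        rows.append({"K": K, "accuracy": correct / n, "n_decisions": n})
    return pd.DataFrame(rows)


def export_report(
    report: EvalReport,
    out_dir: str | Path,
    *,
    class_names: Sequence[str] = EXERCISE_CLASS_NAMES,
    stem: str = "report",
) -> dict[str, Path]:
    """Write a report as JSON + Markdown + confusion-matrix CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": out_dir / f"{stem}.json",
        "markdown": out_dir / f"{stem}.md",
        "confusion": out_dir / f"{stem}_confusion.csv",
    }
    paths["json"].write_text(json.dumps(report.to_dict(), indent=2))
    paths["markdown"].write_text(report.to_markdown(class_names) + "\n")
    n = report.confusion.shape[0]
    names = [class_names[i] if i < len(class_names) else str(i) for i in range(n)]
    pd.DataFrame(report.confusion, index=names, columns=names).to_csv(
        paths["confusion"], index_label="true\\pred"
    )
    return paths
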