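"""Soft-voting aggregation of per-frame class probabilities.

A single frame can be ambiguous or outright corrupted (a pose-estimator
glitch), so the classifier's per-frame probability vectors are pooled over
a window of K consecutive frames (default 30): the vectors are summed
element-wise and the argmax of the sums is the window's decision.  Summing
and averaging are equivalent under argmax; ties break to the lowest class
index.  Windows advance by a configurable stride — the default stride K
gives non-overlapping verdicts (one decision per 30 frames); stride 1
gives a sliding, latency-minimizing stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .landmarks import ExerciseClass, PoseSequence, exercise_class
from .features import DEFAULT_ANGLES, AngleSpec, extract_sequence_features, feature_matrix
from .cnn import ClassProbabilities, TrainedModel, predict_batch

__all__ = [
    "EnsembleConfig",
    "EnsembleDecision",
    "soft_vote",
    "classify_stream",
    "classify_sequence",
    "export_decisions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleConfig:
    """Window length K (frames per decision) and stride between windows."""

    window_frames: int = 30
    stride: Optional[int] = None  # None -> non-overlapping (stride = K)

    def __post_init__(self) -> None:
        if self.window_frames < 1:
            raise ValueError(f"window_frames must be >= 1, got {self.window_frames}")
        if self.stride is not None and self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")

    @property
    def effective_stride(self) -> int:
        return self.window_frames if self.stride is None else self.stride


@dataclass
class EnsembleDecision:
    """One window's verdict: aggregated scores over [window_start,
    window_end) and the argmax class (lowest index on ties)."""

    window_start: int
    window_end: int
    scores: np.ndarray
    predicted: ExerciseClass


def soft_vote(
    probs: Sequence[ClassProbabilities | np.ndarray],
    window_start: int = 0,
    window_end: Optional[int] = None,
) -> EnsembleDecision:
    """Sum per-frame probability vectors and pick the argmax class.

    NaN vectors (frames whose feature extraction failed in lenient mode)
    are excluded from the vote; a window with zero valid frames raises.
    """
    if len(probs) == 0:
        raise ValueError("cannot vote over an empty window")
    rows = np.stack(
        [p.probs if isinstance(p, ClassProbabilities) else np.asarray(p, dtype=np.float64)
         for p in probs]
    )
    if rows.ndim != 2:
        raise ValueError("probability vectors have mismatched lengths")
    valid = ~np.isnan(rows).any(axis=1)
    if not valid.any():
        raise ValueError("window has no valid frames to vote over")
    scores = rows[valid].sum(axis=0)
    predicted = exercise_class(int(np.argmax(scores)))  # argmax -> first max
    return EnsembleDecision(
        window_start=window_start,
        window_end=len(probs) if window_end is None else window_end,
        scores=scores,
        predicted=predicted,
    )


def classify_stream(
    model: TrainedModel,
    seq: PoseSequence,
    cfg: EnsembleConfig = EnsembleConfig(),
    *,
    specs: Sequence[AngleSpec] = DEFAULT_ANGLES,
    standardize: bool = False,
    degenerate: str = "strict",
) -> list[EnsembleDecision]:
    """Classify a sequence window by window.

    Features are extracted per frame, per-frame probabilities computed,
    and each window of K frames (advancing by the stride) yields one
    decision.  Sequences shorter than K yield no decisions (logged).
    """
    feats = extract_sequence_features(
        seq, specs, standardize=standardize, degenerate=degenerate
    )
    X = feature_matrix(feats)
    nan_rows = np.isnan(X).any(axis=1)
    if nan_rows.any():
        logger.warning(
            "sequence %s: %d frame(s) with undefined features excluded from voting",
            seq.sequence_id, int(nan_rows.sum()),
        )
    probs = np.full((X.shape[0], model.config.n_classes), np.nan)
    if (~nan_rows).any():
        probs[~nan_rows] = predict_batch(model, X[~nan_rows])

    K, stride = cfg.window_frames, cfg.effective_stride
    n = X.shape[0]
    decisions: list[EnsembleDecision] = []
    if n < K:
        logger.warning(
            "sequence %s has %d frames, shorter than window %d: no decisions",
            seq.sequence_id, n, K,
        )
        return decisions
    for start in range(0, n - K + 1, stride):
        window = probs[start : start + K]
        if np.isnan(window).all():
            logger.warning(
                "sequence %s window [%d,%d): no valid frames, skipped",
                seq.sequence_id, start, start + K,
            )
            continue
        decisions.append(
            soft_vote(list(window), window_start=start, window_end=start + K)
        )
    return decisions


def classify_sequence(
    model: TrainedModel,
    seq: PoseSequence,
    cfg: EnsembleConfig = EnsembleConfig(),
    **feature_opts,
) -> ExerciseClass:
    """Whole-sequence verdict: majority class over window decisions, ties
    broken by total summed scores then lowest index.  A sequence shorter
    than K falls back to one soft vote over all its frames."""
    decisions = classify_stream(model, seq, cfg, **feature_opts)
    if not decisions:
        fallback = EnsembleConfig(window_frames=len(seq), stride=None)
        decisions = classify_stream(model, seq, fallback, **feature_opts)
        if not decisions:
            raise ValueError(f"sequence {seq.sequence_id!r}: no classifiable frames")
    n_classes = decisions[0].scores.size
    votes = np.zeros(n_classes)
    totals = np.zeros(n_classes)
    for d in decisions:
        votes[d.predicted.index] += 1
        totals += d.scores
    best = np.flatnonzero(votes == votes.max())
    if best.size > 1:
        best = best[np.argsort(-totals[best], kind="stable")]
    return exercise_class(int(best[0]))


def export_decisions(
    seq: PoseSequence, decisions: Sequence[EnsembleDecision], path: str | Path
) -> Path:
    """Write decisions as CSV: ``sequence_id,window_start,window_end,
    predicted,score_0...score_9``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_scores = decisions[0].scores.size if decisions else 10
    cols = ["sequence_id", "window_start", "window_end", "predicted"] + [
        f"score_{i}" for i in range(n_scores)
    ]
    rows = [
        [seq.sequence_id, d.window_start, d.window_end, d.predicted.name, *d.scores]
        for d in decisions
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path
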