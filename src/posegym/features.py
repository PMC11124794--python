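"""Per-frame feature engineering: 66 raw coordinates + 12 joint angles.

Each frame contributes 22 landmarks x (x, y, z) = 66 coordinate features,
followed by one angle in degrees per configured joint (12 by default),
giving the 78-attribute vector the classifier consumes.

A joint angle at vertex p2 between segments p2-p1 and p2-p3 is computed by
the law of cosines from the three pairwise Euclidean distances a = |p1 p2|,
b = |p2 p3|, c = |p3 p1|:

    angle(p1, p2, p3) = (180 / pi) * acos((a^2 + b^2 - c^2) / (2 a b))

The acos argument is clamped to [-1, 1] to guard floating-point overshoot
on near-collinear joints.  Angles are translation-, rotation- and
scale-invariant, so coordinate standardization (optional, off by default)
never touches the angle block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .landmarks import (
    LANDMARK_INDEX,
    LANDMARK_NAMES,
    LandmarkFrame,
    Point3D,
    PoseSequence,
    ValidationError,
)

__all__ = [
    "AngleSpec",
    "DEFAULT_ANGLES",
    "FrameFeatures",
    "DegenerateJointError",
    "euclidean_distance",
    "joint_angle",
    "extract_frame_features",
    "extract_sequence_features",
    "feature_matrix",
    "export_feature_matrix",
    "N_COORDINATE_FEATURES",
]

N_COORDINATE_FEATURES = 3 * len(LANDMARK_NAMES)  # 66


class DegenerateJointError(ValueError):
    """Two landmarks of an angle spec coincide, so the angle is undefined."""


@dataclass(frozen=True)
class AngleSpec:
    """A named joint angle: the angle at vertex ``p2`` between the rays
    towards ``p1`` and ``p3``."""

    name: str
    p1: str
    p2: str
    p3: str

    def __post_init__(self) -> None:
        names = (self.p1, self.p2, self.p3)
        if len(set(names)) != 3:
            raise ValidationError(f"angle {self.name!r}: landmark names must be distinct")
        for n in names:
            if n not in LANDMARK_INDEX:
                raise ValidationError(f"angle {self.name!r}: unknown landmark {n!r}")


def _bilateral(name: str, p1: str, p2: str, p3: str) -> tuple[AngleSpec, AngleSpec]:
    return (
        AngleSpec(f"left_{name}", f"left_{p1}", f"left_{p2}", f"left_{p3}"),
        AngleSpec(f"right_{name}", f"right_{p1}", f"right_{p2}", f"right_{p3}"),
    )


#: The 12 default joint angles: elbow, shoulder, hip, knee, ankle and wrist
#: on both sides — the major limb joints resolvable from the 22-landmark set.
DEFAULT_ANGLES: tuple[AngleSpec, ...] = (
    *_bilateral("elbow", "shoulder", "elbow", "wrist"),
    *_bilateral("shoulder", "elbow", "shoulder", "hip"),
    *_bilateral("hip", "shoulder", "hip", "knee"),
    *_bilateral("knee", "hip", "knee", "ankle"),
    *_bilateral("ankle", "knee", "ankle", "foot_index"),
    *_bilateral("wrist", "elbow", "wrist", "index"),
)


@dataclass
class FrameFeatures:
    """One frame's feature vector: 66 ordered coordinates then one angle
    (degrees) per spec; ``vector`` is their concatenation."""

    frame_index: int
    coordinates: np.ndarray  # (66,)
    angles: np.ndarray       # (n_specs,)

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.coordinates, self.angles])

    def __len__(self) -> int:
        return self.coordinates.size + self.angles.size


def euclidean_distance(p: Point3D, q: Point3D) -> float:
    """Straight-line distance between two landmarks (body-part length)."""
    return math.dist(p.as_tuple(), q.as_tuple())


def joint_angle(
    p1: Point3D, p2: Point3D, p3: Point3D, *, degenerate: str = "strict"
) -> float:
    """Law-of-cosines angle at vertex ``p2``, in degrees within [0, 180].

    ``degenerate`` controls the zero-length-segment case: ``"strict"``
    raises :class:`DegenerateJointError`, ``"nan"`` returns NaN.
    """
    a = euclidean_distance(p1, p2)
    b = euclidean_distance(p2, p3)
    if a == 0.0 or b == 0.0:
        if degenerate == "nan":
            return float("nan")
        raise DegenerateJointError(
            f"coincident landmarks at joint vertex ({p2}); angle undefined"
        )
    c = euclidean_distance(p3, p1)
    cos_arg = (a * a + b * b - c * c) / (2.0 * a * b)
    cos_arg = min(1.0, max(-1.0, cos_arg))
    return math.degrees(math.acos(cos_arg))


def extract_frame_features(
    frame: LandmarkFrame,
    specs: Sequence[AngleSpec] = DEFAULT_ANGLES,
    *,
    degenerate: str = "strict",
    coordinate_shift: Optional[np.ndarray] = None,
    coordinate_scale: Optional[np.ndarray] = None,
) -> FrameFeatures:
    """Assemble one frame's feature vector.

    Coordinates come first in registry order (x, y, z per landmark), then
    the angles in spec order.  ``coordinate_shift``/``coordinate_scale``
    are optional per-coordinate standardization statistics supplied by the
    caller (see :func:`extract_sequence_features`); angles are never
    standardized.
    """
    coords = np.fromiter(
        (c for n in LANDMARK_NAMES for c in frame.landmarks[n].as_tuple()),
        dtype=np.float64,
        count=N_COORDINATE_FEATURES,
    )
    if coordinate_shift is not None:
        coords = coords - coordinate_shift
    if coordinate_scale is not None:
        coords = coords / coordinate_scale
    angles = np.array(
        [
            joint_angle(frame[s.p1], frame[s.p2], frame[s.p3], degenerate=degenerate)
            for s in specs
        ],
        dtype=np.float64,
    )
    return FrameFeatures(frame.frame_index, coords, angles)


def extract_sequence_features(
    seq: PoseSequence,
    specs: Sequence[AngleSpec] = DEFAULT_ANGLES,
    *,
    standardize: bool = False,
    degenerate: str = "strict",
) -> list[FrameFeatures]:
    """Extract features for every frame of a sequence, in order.

    With ``standardize=True``, each of the 66 coordinate columns is shifted
    to zero mean and scaled to unit standard deviation across the
    sequence's frames (constant columns are left unscaled).
    """
    shift = scale = None
    if standardize:
        mat = np.stack(
            [
                np.fromiter(
                    (c for n in LANDMARK_NAMES for c in f.landmarks[n].as_tuple()),
                    dtype=np.float64,
                    count=N_COORDINATE_FEATURES,
                )
                for f in seq.frames
            ]
        )
        shift = mat.mean(axis=0)
        scale = mat.std(axis=0)
        # columns that are constant up to float accumulation error are
        # centred but not scaled
        constant = scale <= 1e-12 * np.maximum(1.0, np.abs(shift))
        scale[constant] = 1.0
    return [
        extract_frame_features(
            f, specs, degenerate=degenerate,
            coordinate_shift=shift, coordinate_scale=scale,
        )
        for f in seq.frames
    ]


def feature_matrix(features: Iterable[FrameFeatures]) -> np.ndarray:
    """Stack per-frame feature vectors into an (n_frames, n_features) array."""
    return np.stack([f.vector for f in features])


def export_feature_matrix(
    seq: PoseSequence,
    features: Sequence[FrameFeatures],
    path: str | Path,
) -> Path:
    """Write a sequence's features as CSV with columns
    ``sequence_id,frame,f000...fNNN``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mat = feature_matrix(features)
    cols = [f"f{i:03d}" for i in range(mat.shape[1])]
    df = pd.DataFrame(mat, columns=cols)
    df.insert(0, "frame", [f.frame_index for f in features])
    df.insert(0, "sequence_id", seq.sequence_id)
    df.to_csv(path, index=False)
    return path
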