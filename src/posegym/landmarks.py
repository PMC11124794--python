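"""Pose-landmark data model and file I/O.

The data model follows the MediaPipe Pose convention: of the 33 landmarks
the estimator emits, only the 22 non-facial body points (indices 11-32) are
kept.  Sequences are stored as plain CSV (one row per landmark per frame)
or JSONL (one frame object per line), so raw landmark dumps from any pose
estimator load directly — facial rows, if present, are silently dropped.

Coordinates may be image-normalized or metric; only finiteness is
validated, because all downstream angle features are scale- and
translation-invariant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "Point3D",
    "LandmarkFrame",
    "PoseSequence",
    "ExerciseClass",
    "LANDMARK_NAMES",
    "LANDMARK_INDEX",
    "EXERCISE_CLASSES",
    "exercise_class",
    "read_sequence",
    "write_sequence",
    "read_manifest",
    "write_manifest",
    "ValidationError",
    "ParseError",
]


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


class ParseError(ValueError):
    """A file row could not be parsed."""


# MediaPipe Pose indices 11-32: the 22 non-facial body landmarks, in
# estimator order.  This tuple fixes the coordinate-block ordering of the
# feature vector, so it must never be reordered.
LANDMARK_NAMES: tuple[str, ...] = (
    "left_shoulder",      # 11
    "right_shoulder",     # 12
    "left_elbow",         # 13
    "right_elbow",        # 14
    "left_wrist",         # 15
    "right_wrist",        # 16
    "left_pinky",         # 17
    "right_pinky",        # 18
    "left_index",         # 19
    "right_index",        # 20
    "left_thumb",         # 21
    "right_thumb",        # 22
    "left_hip",           # 23
    "right_hip",          # 24
    "left_knee",          # 25
    "right_knee",         # 26
    "left_ankle",         # 27
    "right_ankle",        # 28
    "left_heel",          # 29
    "right_heel",         # 30
    "left_foot_index",    # 31
    "right_foot_index",   # 32
)

#: name -> MediaPipe Pose index (bijection over {11..32})
LANDMARK_INDEX: dict[str, int] = {n: i + 11 for i, n in enumerate(LANDMARK_NAMES)}
#: MediaPipe Pose index -> name
INDEX_LANDMARK: dict[int, str] = {v: k for k, v in LANDMARK_INDEX.items()}

#: The ten exercise classes, in alphabetical order; index = position.
EXERCISE_CLASS_NAMES: tuple[str, ...] = (
    "arm_raise",
    "bicycle_crunch",
    "bird_dog",
    "curl",
    "fly",
    "leg_raise",
    "overhead_press",
    "push_up",
    "squat",
    "superman",
)


@dataclass(frozen=True)
class ExerciseClass:
    """One of the ten exercise labels; ``index`` is its position in the
    alphabetical registry (0-9)."""

    name: str
    index: int

    def __post_init__(self) -> None:
        if self.name not in EXERCISE_CLASS_NAMES:
            raise ValidationError(
                f"unknown exercise class {self.name!r}; accepted: "
                f"{', '.join(EXERCISE_CLASS_NAMES)}"
            )
        if EXERCISE_CLASS_NAMES[self.index] != self.name:
            raise ValidationError(
                f"class index {self.index} does not match name {self.name!r}"
            )


EXERCISE_CLASSES: tuple[ExerciseClass, ...] = tuple(
    ExerciseClass(n, i) for i, n in enumerate(EXERCISE_CLASS_NAMES)
)
N_CLASSES = len(EXERCISE_CLASSES)


def exercise_class(name_or_index: str | int) -> ExerciseClass:
    """Look up an :class:`ExerciseClass` by name or registry index."""
    if isinstance(name_or_index, int):
        if not 0 <= name_or_index < N_CLASSES:
            raise ValidationError(f"class index out of range: {name_or_index}")
        return EXERCISE_CLASSES[name_or_index]
    # tolerate human spellings like "push-up" / "arm raise"
    key = name_or_index.strip().lower().replace("-", "_").replace(" ", "_")
    if key not in EXERCISE_CLASS_NAMES:
        raise ValidationError(
            f"unknown exercise class {name_or_index!r}; accepted: "
            f"{', '.join(EXERCISE_CLASS_NAMES)}"
        )
    return EXERCISE_CLASSES[EXERCISE_CLASS_NAMES.index(key)]


@dataclass(frozen=True)
class Point3D:
    """A 3-D landmark position (x, y image-plane, z relative depth)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            c = getattr(self, name)
            try:
                c = float(c)
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"non-numeric coordinate {name}={c!r}") from exc
            if not math.isfinite(c):
                raise ValidationError(f"non-finite coordinate {name}={c!r}")
            object.__setattr__(self, name, c)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class LandmarkFrame:
    """One frame's 22 named body landmarks, plus optional per-landmark
    visibility confidences in [0, 1]."""

    frame_index: int
    landmarks: dict[str, Point3D]
    visibility: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"negative frame index {self.frame_index}")
        missing = [n for n in LANDMARK_NAMES if n not in self.landmarks]
        extra = [n for n in self.landmarks if n not in LANDMARK_INDEX]
        if missing or extra:
            raise ValidationError(
                f"frame {self.frame_index}: expected exactly the 22 body "
                f"landmarks; missing={missing}, unexpected={extra}"
            )
        # keep registry order regardless of insertion order
        self.landmarks = {n: self.landmarks[n] for n in LANDMARK_NAMES}
        if self.visibility is not None:
            for n, v in self.visibility.items():
                if n not in LANDMARK_INDEX:
                    raise ValidationError(f"visibility for unknown landmark {n!r}")
                if not (0.0 <= v <= 1.0):
                    raise ValidationError(f"visibility out of [0,1]: {n}={v}")

    def __getitem__(self, name: str) -> Point3D:
        return self.landmarks[name]


@dataclass
class PoseSequence:
    """An ordered, non-empty series of landmark frames at a fixed frame
    rate; the unit of train/test splitting."""

    sequence_id: str
    frames: list[LandmarkFrame]
    fps: float = 30.0
    label: Optional[ExerciseClass] = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError(f"sequence {self.sequence_id!r} has no frames")
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"sequence {self.sequence_id!r}: frame_index not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["sequence_id", "frame", "landmark", "x", "y", "z", "visibility"]


def _landmark_name(raw: object, line: int) -> Optional[str]:
    """Resolve a landmark cell (name or MediaPipe index) to a registry name.

    Returns None for facial landmarks (indices 0-10), which callers drop.
    """
    s = str(raw).strip()
    if s.lstrip("-").isdigit():
        idx = int(s)
        if 0 <= idx <= 10:
            return None
        if idx in INDEX_LANDMARK:
            return INDEX_LANDMARK[idx]
        raise ParseError(f"line {line}: landmark index {idx} outside 0-32")
    key = s.lower()
    if key in LANDMARK_INDEX:
        return key
    # facial landmark names from the full 33-point convention
    facial = {
        "nose", "left_eye_inner", "left_eye", "left_eye_outer",
        "right_eye_inner", "right_eye", "right_eye_outer",
        "left_ear", "right_ear", "mouth_left", "mouth_right",
    }
    if key in facial:
        return None
    raise ParseError(f"line {line}: unknown landmark {raw!r}")


def read_sequence(path: str | Path, format: Optional[str] = None) -> PoseSequence:
    """Read a :class:`PoseSequence` from a landmark CSV or JSONL file.

    Facial landmarks present in the file are silently dropped; after
    dropping, every frame must contain exactly the 22 body landmarks.
    The format is inferred from the suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson"} else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "jsonl":
        return _read_jsonl(path)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> PoseSequence:
    try:
        df = pd.read_csv(path, dtype={"sequence_id": str}, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    required = {"sequence_id", "frame", "landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if df.empty:
        raise ValidationError(f"{path}: no landmark rows")
    has_vis = "visibility" in df.columns
    seq_ids = df["sequence_id"].unique()
    if len(seq_ids) != 1:
        raise ParseError(f"{path}: expected one sequence_id, found {list(seq_ids)}")

    frames: list[LandmarkFrame] = []
    for frame_idx, grp in df.groupby("frame", sort=True):
        pts: dict[str, Point3D] = {}
        vis: dict[str, float] = {}
        for row in grp.itertuples():
            line = row.Index + 2  # header + 0-based
            name = _landmark_name(row.landmark, line)
            if name is None:
                continue
            try:
                pts[name] = Point3D(float(row.x), float(row.y), float(row.z))
            except (TypeError, ValueError, ValidationError) as exc:
                raise ParseError(f"line {line}: bad coordinates ({exc})") from exc
            if has_vis and not pd.isna(row.visibility):
                vis[name] = float(row.visibility)
        frames.append(
            LandmarkFrame(int(frame_idx), pts, visibility=vis or None)
        )
    return PoseSequence(sequence_id=str(seq_ids[0]), frames=frames)


def _read_jsonl(path: Path) -> PoseSequence:
    frames: list[LandmarkFrame] = []
    seq_id: Optional[str] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                obj = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise ParseError(f"line {lineno}: invalid JSON ({exc})") from exc
            try:
                sid = str(obj["sequence_id"])
                fidx = int(obj["frame"])
                lm = obj["landmarks"]
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"line {lineno}: malformed frame object ({exc})") from exc
            if seq_id is None:
                seq_id = sid
            elif sid != seq_id:
                raise ParseError(f"line {lineno}: sequence_id changed mid-file")
            pts: dict[str, Point3D] = {}
            vis: dict[str, float] = {}
            for name_raw, coords in lm.items():
                name = _landmark_name(name_raw, lineno)
                if name is None:
                    continue
                if not isinstance(coords, (list, tuple)) or len(coords) not in (3, 4):
                    raise ParseError(
                        f"line {lineno}: landmark {name_raw!r} needs [x,y,z] or [x,y,z,visibility]"
                    )
                pts[name] = Point3D(float(coords[0]), float(coords[1]), float(coords[2]))
                if len(coords) == 4:
                    vis[name] = float(coords[3])
            frames.append(LandmarkFrame(fidx, pts, visibility=vis or None))
    if seq_id is None:
        raise ValidationError(f"{path}: no frames")
    frames.sort(key=lambda f: f.frame_index)
    return PoseSequence(sequence_id=seq_id, frames=frames)


def write_sequence(seq: PoseSequence, path: str | Path, format: Optional[str] = None) -> Path:
    """Write a sequence so that :func:`read_sequence` reproduces it exactly
    (coordinates are serialized with 17 significant digits)."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson"} else "csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        rows = []
        for frame in seq.frames:
            for name, p in frame.landmarks.items():
                v = None
                if frame.visibility is not None and name in frame.visibility:
                    v = repr(frame.visibility[name])
                rows.append(
                    (seq.sequence_id, frame.frame_index, name,
                     repr(p.x), repr(p.y), repr(p.z), v)
                )
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for frame in seq.frames:
                lm: dict[str, list[float]] = {}
                for name, p in frame.landmarks.items():
                    coords = [p.x, p.y, p.z]
                    if frame.visibility is not None and name in frame.visibility:
                        coords.append(frame.visibility[name])
                    lm[name] = coords
                fh.write(json.dumps(
                    {"sequence_id": seq.sequence_id, "frame": frame.frame_index,
                     "landmarks": lm}
                ) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_manifest(path: str | Path) -> list[tuple[Path, ExerciseClass, str]]:
    """Read a dataset manifest CSV (``sequence_id,label,path``).

    Returns (sequence path, class, sequence_id) triples; relative paths are
    resolved against the manifest's directory.  Unknown labels and duplicate
    sequence ids are validation errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"sequence_id", "label", "path"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: manifest needs columns {sorted(required)}")
    dupes = df["sequence_id"][df["sequence_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate sequence_id(s): {sorted(set(dupes))}")
    out = []
    for row in df.itertuples():
        cls = exercise_class(row.label)
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        out.append((p, cls, str(row.sequence_id)))
    return out


def write_manifest(entries: Iterable[tuple[str, str, str]], path: str | Path) -> Path:
    """Write a manifest CSV from (sequence_id, label, path) triples."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(list(entries), columns=["sequence_id", "label", "path"])
    df.to_csv(path, index=False)
    return path
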