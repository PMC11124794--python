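"""Synthetic skeleton-motion generator.

Generates labelled landmark sequences with class-specific periodic
joint-angle signatures, so the full pipeline (features -> CNN -> ensemble)
can be trained and evaluated with no external data.  Each exercise class
is a caricature of the real movement: a set of per-joint sinusoids
(baseline + amplitude * sin(2*pi*f*t + phase)) over the twelve default
joints, e.g. a squat oscillates knees and hips through ~110 degrees while
a curl moves only the elbows.

Geometry.  Landmark positions follow from the commanded angles by forward
kinematics over fixed segment lengths.  Each body side is laid out in its
own sagittal plane at a constant depth offset (left +z, right -z), and
every default angle spec involves landmarks of one side only, so the
commanded angle at each joint is exactly the angle the feature extractor
re-measures (the generator and extractor are mutual oracles).  Full 3-D
choreography is deliberately out of scope.

Noise.  Gaussian jitter is added to every coordinate, and with a small
probability a whole frame is replaced by a corrupted one (jitter at 10x
sigma) — emulating the pose-estimator glitches the frame ensemble is
designed to absorb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .landmarks import (
    EXERCISE_CLASS_NAMES,
    ExerciseClass,
    LandmarkFrame,
    Point3D,
    PoseSequence,
    exercise_class,
    write_manifest,
    write_sequence,
)

__all__ = [
    "SkeletonTemplate",
    "JointOscillation",
    "ClassSignature",
    "NoiseModel",
    "DEFAULT_SIGNATURES",
    "simulate_sequence",
    "simulate_dataset",
    "load_signatures",
    "save_signatures",
    "validate_signature_distinctness",
]

#: the twelve signature joints, matching features.DEFAULT_ANGLES order
JOINT_NAMES = (
    "left_elbow", "right_elbow",
    "left_shoulder", "right_shoulder",
    "left_hip", "right_hip",
    "left_knee", "right_knee",
    "left_ankle", "right_ankle",
    "left_wrist", "right_wrist",
)


@dataclass(frozen=True)
class SkeletonTemplate:
    """Fixed segment lengths (arbitrary units; defaults roughly metric).

    The two body sides are laid out in parallel planes whose depth
    separation is the mean of shoulder and hip width.
    """

    shoulder_width: float = 0.38
    hip_width: float = 0.34
    torso: float = 0.50
    upper_arm: float = 0.30
    forearm: float = 0.27
    hand: float = 0.18
    thigh: float = 0.45
    shank: float = 0.42
    foot: float = 0.22

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"segment length {name} must be positive, got {v}")

    @property
    def side_offset(self) -> float:
        return 0.25 * (self.shoulder_width + self.hip_width)


@dataclass(frozen=True)
class JointOscillation:
    """One joint's sinusoid: angle(t) = baseline + amplitude *
    sin(2*pi*frequency*t + phase), degrees / Hz / radians."""

    baseline: float
    amplitude: float = 0.0
    frequency: float = 0.5
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")

    def angle(self, t: np.ndarray) -> np.ndarray:
        return self.baseline + self.amplitude * np.sin(
            2.0 * math.pi * self.frequency * t + self.phase
        )


@dataclass
class ClassSignature:
    """Per-joint oscillation parameters for one exercise class."""

    name: str
    joints: dict[str, JointOscillation]

    def __post_init__(self) -> None:
        missing = [j for j in JOINT_NAMES if j not in self.joints]
        if missing:
            raise ValueError(f"signature {self.name!r} missing joints: {missing}")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian coordinate noise plus occasional outlier frames
    (whole-frame jitter at 10x sigma), emulating estimator glitches."""

    coordinate_sigma: float = 0.005
    outlier_rate: float = 0.05
    outlier_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.coordinate_sigma < 0:
            raise ValueError("coordinate_sigma must be >= 0")
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ValueError("outlier_rate must be in [0,1)")


def _sym(
    elbow, shoulder, hip, knee, ankle, wrist, freq, *, antiphase: Sequence[str] = ()
) -> dict[str, JointOscillation]:
    """Build a bilaterally symmetric joint map from (baseline, amplitude)
    pairs; joints named in ``antiphase`` get the right side half a cycle
    out of phase (pedalling-type movements)."""
    out: dict[str, JointOscillation] = {}
    for joint, (base, amp) in zip(
        ("elbow", "shoulder", "hip", "knee", "ankle", "wrist"),
        (elbow, shoulder, hip, knee, ankle, wrist),
    ):
        for side in ("left", "right"):
            phase = math.pi if (side == "right" and joint in antiphase) else 0.0
            out[f"{side}_{joint}"] = JointOscillation(base, amp, freq, phase)
    return out


# Hand-designed caricatures of the ten exercises.  For every pair of
# classes at least one joint differs by >= 15 degrees in baseline or
# amplitude (validated by validate_signature_distinctness).
DEFAULT_SIGNATURES: dict[str, ClassSignature] = {
    name: ClassSignature(name, joints)
    for name, joints in {
        "arm_raise": _sym((170, 5), (90, 70), (175, 2), (175, 2), (90, 3), (170, 3), 0.50),
        "bicycle_crunch": _sym(
            (90, 10), (40, 8), (110, 40), (100, 50), (95, 5), (170, 2), 0.60,
            antiphase=("hip", "knee"),
        ),
        "bird_dog": _sym(
            (170, 5), (120, 50), (140, 35), (140, 30), (100, 5), (170, 2), 0.40,
            antiphase=("shoulder", "hip", "knee"),
        ),
        "curl": _sym((90, 60), (15, 5), (175, 2), (175, 2), (90, 3), (175, 3), 0.50),
        "fly": _sym((145, 20), (85, 12), (175, 2), (175, 2), (90, 3), (155, 8), 0.45),
        "leg_raise": _sym((170, 3), (30, 5), (130, 42), (172, 4), (120, 5), (170, 2), 0.50),
        "overhead_press": _sym((115, 50), (140, 35), (175, 2), (175, 2), (90, 3), (175, 2), 0.50),
        "push_up": _sym((120, 55), (45, 18), (168, 4), (175, 2), (70, 5), (90, 5), 0.55),
        "squat": _sym((160, 5), (60, 10), (120, 48), (120, 55), (80, 12), (170, 2), 0.45),
        "superman": _sym((170, 4), (160, 14), (158, 14), (170, 4), (110, 5), (170, 2), 0.45),
    }.items()
}


def validate_signature_distinctness(
    signatures: dict[str, ClassSignature], min_separation: float = 15.0
) -> None:
    """Every class pair must differ by >= ``min_separation`` degrees in
    baseline or amplitude on at least one joint."""
    names = sorted(signatures)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sep = max(
                max(
                    abs(signatures[a].joints[j].baseline - signatures[b].joints[j].baseline),
                    abs(signatures[a].joints[j].amplitude - signatures[b].joints[j].amplitude),
                )
                for j in JOINT_NAMES
            )
            if sep < min_separation:
                raise ValueError(
                    f"signatures {a!r} and {b!r} are not distinct "
                    f"(max separation {sep:.1f} < {min_separation} deg)"
                )


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------


def _rotate(u: np.ndarray, deg: float) -> np.ndarray:
    """Rotate an in-plane 2-D vector by ``deg`` degrees; the angle between
    u and the result is |deg| (mod 360), which for deg in (0, 180) equals
    the commanded joint angle."""
    r = math.radians(deg)
    c, s = math.cos(r), math.sin(r)
    return np.array([u[0] * c - u[1] * s, u[0] * s + u[1] * c])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _side_chain(
    angles: dict[str, float], template: SkeletonTemplate, z: float, side: str
) -> dict[str, Point3D]:
    """Place one side's 11 landmarks in its sagittal plane from the six
    commanded joint angles."""
    t = template
    hip = np.array([0.0, 0.0])
    shoulder = hip + np.array([0.0, t.torso])

    up = _unit(shoulder - hip)
    thigh_dir = _rotate(up, angles[f"{side}_hip"])
    knee = hip + t.thigh * thigh_dir
    shank_dir = _rotate(_unit(hip - knee), angles[f"{side}_knee"])
    ankle = knee + t.shank * shank_dir
    foot_dir = _rotate(_unit(knee - ankle), angles[f"{side}_ankle"])
    foot_index = ankle + t.foot * foot_dir
    heel = ankle - 0.35 * t.foot * foot_dir

    down = _unit(hip - shoulder)
    upper_dir = _rotate(down, angles[f"{side}_shoulder"])
    elbow = shoulder + t.upper_arm * upper_dir
    fore_dir = _rotate(_unit(shoulder - elbow), angles[f"{side}_elbow"])
    wrist = elbow + t.forearm * fore_dir
    hand_ref = _unit(elbow - wrist)
    index = wrist + t.hand * _rotate(hand_ref, angles[f"{side}_wrist"])
    pinky = wrist + 0.95 * t.hand * _rotate(hand_ref, angles[f"{side}_wrist"] + 12.0)
    thumb = wrist + 0.65 * t.hand * _rotate(hand_ref, angles[f"{side}_wrist"] - 12.0)

    pts2d = {
        "shoulder": shoulder, "elbow": elbow, "wrist": wrist,
        "pinky": pinky, "index": index, "thumb": thumb,
        "hip": hip, "knee": knee, "ankle": ankle,
        "heel": heel, "foot_index": foot_index,
    }
    return {
        f"{side}_{name}": Point3D(float(p[0]), float(p[1]), z)
        for name, p in pts2d.items()
    }


def _clamp_angles(a: np.ndarray, lo: float = 2.0, hi: float = 178.0) -> np.ndarray:
    return np.clip(a, lo, hi)


def simulate_sequence(
    cls: ExerciseClass | str,
    n_frames: int = 120,
    fps: float = 30.0,
    template: SkeletonTemplate = SkeletonTemplate(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    *,
    signatures: Optional[dict[str, ClassSignature]] = None,
    sequence_id: Optional[str] = None,
    return_angles: bool = False,
):
    """Simulate one labelled landmark sequence.

    A per-sequence random phase offset (common to all joints, preserving
    antiphase relations) and a mild frequency scaling make repeats of one
    class distinct; identical seeds give bit-identical output.  With
    ``return_angles=True`` also returns the realized (pre-noise) joint
    trajectories as an (n_frames, 12) array in JOINT_NAMES order.
    """
    if n_frames < 1:
        raise ValueError(f"n_frames must be >= 1, got {n_frames}")
    cls = exercise_class(cls) if isinstance(cls, str) else cls
    signatures = DEFAULT_SIGNATURES if signatures is None else signatures
    if cls.name not in signatures:
        raise ValueError(f"no signature for class {cls.name!r}")
    sig = signatures[cls.name]
    rng = np.random.default_rng(seed)

    phase_offset = rng.uniform(0.0, 2.0 * math.pi)
    freq_scale = rng.uniform(0.9, 1.1)
    t = np.arange(n_frames) / fps
    angles = np.empty((n_frames, len(JOINT_NAMES)))
    for j, joint in enumerate(JOINT_NAMES):
        osc = sig.joints[joint]
        scaled = JointOscillation(
            osc.baseline, osc.amplitude, osc.frequency * freq_scale,
            osc.phase + phase_offset,
        )
        angles[:, j] = _clamp_angles(scaled.angle(t))

    frames: list[LandmarkFrame] = []
    z = template.side_offset
    for i in range(n_frames):
        frame_angles = dict(zip(JOINT_NAMES, angles[i]))
        pts = {
            **_side_chain(frame_angles, template, +z, "left"),
            **_side_chain(frame_angles, template, -z, "right"),
        }
        sigma = noise.coordinate_sigma
        if sigma > 0 and rng.random() < noise.outlier_rate:
            sigma = sigma * noise.outlier_factor
        if sigma > 0:
            jitter = rng.normal(0.0, sigma, size=(len(pts), 3))
            pts = {
                name: Point3D(p.x + d[0], p.y + d[1], p.z + d[2])
                for (name, p), d in zip(pts.items(), jitter)
            }
        frames.append(LandmarkFrame(i, pts))

    seq = PoseSequence(
        sequence_id=sequence_id or f"{cls.name}_seed{seed}",
        frames=frames,
        fps=fps,
        label=cls,
    )
    return (seq, angles) if return_angles else seq


def simulate_dataset(
    out_dir: str | Path,
    classes: Sequence[ExerciseClass | str] = EXERCISE_CLASS_NAMES,
    sequences_per_class: int = 5,
    n_frames: int = 120,
    fps: float = 30.0,
    template: SkeletonTemplate = SkeletonTemplate(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    *,
    signatures: Optional[dict[str, ClassSignature]] = None,
    format: str = "csv",
) -> Path:
    """Write a balanced labelled dataset (sequences + manifest) to disk.

    Per-sequence seeds are derived deterministically from the master seed
    and recorded in the manifest's ``seed`` column.  Returns the manifest
    path.
    """
    if sequences_per_class < 1:
        raise ValueError("sequences_per_class must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    classes = [exercise_class(c) if isinstance(c, str) else c for c in classes]
    n_total = len(classes) * sequences_per_class
    child_seeds = np.random.SeedSequence(seed).generate_state(n_total) % (2**31)

    rows = []
    i = 0
    for cls in classes:
        for j in range(sequences_per_class):
            sid = f"{cls.name}_{j:03d}"
            seq = simulate_sequence(
                cls, n_frames, fps, template, noise, int(child_seeds[i]),
                signatures=signatures, sequence_id=sid,
            )
            fname = f"{sid}.{format}"
            write_sequence(seq, out_dir / fname, format=format)
            rows.append((sid, cls.name, fname, int(child_seeds[i])))
            i += 1
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["sequence_id", "label", "path", "seed"]).to_csv(
        manifest, index=False
    )
    return manifest


# ---------------------------------------------------------------------------
# signature registry serialization
# ---------------------------------------------------------------------------


def save_signatures(signatures: dict[str, ClassSignature], path: str | Path) -> Path:
    """Write a signature registry as YAML:
    ``{class: {joint: {baseline, amplitude, frequency, phase}}}``."""
    path = Path(path)
    doc = {
        name: {
            joint: {
                "baseline": osc.baseline,
                "amplitude": osc.amplitude,
                "frequency": osc.frequency,
                "phase": osc.phase,
            }
            for joint, osc in sig.joints.items()
        }
        for name, sig in signatures.items()
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def load_signatures(path: str | Path) -> dict[str, ClassSignature]:
    """Load a YAML signature registry (schema as in :func:`save_signatures`)."""
    doc = yaml.safe_load(Path(path).read_text())
    out: dict[str, ClassSignature] = {}
    for name, joints in doc.items():
        exercise_class(name)  # validates the label
        out[name] = ClassSignature(
            name,
            {
                j: JointOscillation(
                    float(p["baseline"]),
                    float(p.get("amplitude", 0.0)),
                    float(p.get("frequency", 0.5)),
                    float(p.get("phase", 0.0)),
                )
                for j, p in joints.items()
            },
        )
    return out
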