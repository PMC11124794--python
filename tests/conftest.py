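"""Shared fixtures: tiny synthetic sequences and a small trained model.

Everything is generated programmatically at run time from fixed seeds; no
data files ship with the package.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import posegym as pg
from posegym.evaluation import _sequence_frames

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

NOISELESS = pg.NoiseModel(coordinate_sigma=0.0, outlier_rate=0.0)


@pytest.fixture(scope="session")
def squat_sequence() -> pg.PoseSequence:
    """A 40-frame noiseless squat."""
    return pg.simulate_sequence("squat", n_frames=40, noise=NOISELESS, seed=11)


@pytest.fixture(scope="session")
def noisy_sequences() -> list[pg.PoseSequence]:
    """Three 60-frame sequences of different classes with default noise."""
    return [
        pg.simulate_sequence(c, n_frames=60, seed=7 + i, sequence_id=f"{c}_{i}")
        for i, c in enumerate(("arm_raise", "curl", "squat"))
    ]


@pytest.fixture(scope="session")
def small_dataset() -> list[pg.PoseSequence]:
    """10 classes x 3 sequences x 60 frames, default noise."""
    seqs = []
    seeds = np.random.SeedSequence(123).generate_state(30) % (2**31)
    i = 0
    for cls in pg.EXERCISE_CLASSES:
        for j in range(3):
            seqs.append(
                pg.simulate_sequence(
                    cls, n_frames=60, seed=int(seeds[i]),
                    sequence_id=f"{cls.name}_{j:02d}",
                )
            )
            i += 1
    return seqs


@pytest.fixture(scope="session")
def small_model(small_dataset) -> pg.TrainedModel:
    """A 10-class model trained briefly on the small dataset; good enough
    for exercising prediction and ensemble paths (not for accuracy)."""
    model = pg.build_model(pg.ModelConfig(seed=5, epochs=3))
    frames = _sequence_frames(small_dataset, pg.DEFAULT_ANGLES, False)
    pg.train(model, frames, epochs=3, seed=5)
    return model
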