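"""Shared fixtures: everything is generated programmatically and seeded.

The expensive artifacts (a trained small surrogate and its cohort) are
session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecgaudit.surrogate import (
    SurrogateConfig,
    TrainConfig,
    build_surrogate,
    train_surrogate,
)
from ecgaudit.synthetic import MorphologyParams, simulate_cohort, simulate_record

SMALL_FS = 125.0
SMALL_DURATION = 5.0
SMALL_N_SAMPLES = 625

SMALL_MODEL_CONFIG = SurrogateConfig(
    channels=(8, 12, 16, 24),
    kernel=5,
    n_samples=SMALL_N_SAMPLES,
    sampling_rate=SMALL_FS,
    stem_channels=8,
    seed=2,
)

TINY_MODEL_CONFIG = SurrogateConfig(
    channels=(4, 4, 8, 8),
    kernel=3,
    n_samples=250,
    sampling_rate=50.0,
    stem_channels=4,
    seed=5,
)


@pytest.fixture(scope="session")
def neutral_record():
    return simulate_record(MorphologyParams(), fs=SMALL_FS,
                           duration_s=SMALL_DURATION, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(40, 80, fs=SMALL_FS, duration_s=SMALL_DURATION, seed=21)


@pytest.fixture(scope="session")
def trained_small(small_cohort):
    """A small surrogate trained on the shared cohort (plus its history)."""
    model = build_surrogate(SMALL_MODEL_CONFIG)
    model, history = train_surrogate(
        model, small_cohort, TrainConfig(epochs=8, seed=3)
    )
    return model, history


@pytest.fixture(scope="session")
def eval_records(small_cohort):
    records = [r for r, _ in small_cohort[:60]]
    labels = np.array(
        [1 if m.label == "LVSD" else 0 for _, m in small_cohort[:60]]
    )
    return records, labels


@pytest.fixture()
def tiny_model():
    return build_surrogate(TINY_MODEL_CONFIG)
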