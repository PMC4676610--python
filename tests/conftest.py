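"""Shared fixtures: small cohorts, streams, and stub classifiers.

Everything is generated programmatically and seeded; sessions are kept
short (tens of seconds) so the full suite runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

import gaitguard as gg
from gaitguard.forest import ForestConfig
from gaitguard.protocol import ExperimentConfig, TrialConfig
from gaitguard.simulate import SAMPLE_RATE, AdversaryConfig, SensorStream


@pytest.fixture(scope="session")
def cohort():
    return gg.make_cohort(8, 7)


@pytest.fixture(scope="session")
def profile(cohort):
    return cohort[0]


def make_zero_stream(n: int, activity: str = "sitting") -> SensorStream:
    """All-zero stream of n samples, for framing arithmetic tests."""
    return SensorStream(
        subject_id="Z",
        timestamps=np.arange(n) / SAMPLE_RATE,
        accel=np.zeros((n, 3)),
        gyro=np.zeros((n, 3)),
        true_activity=activity,
        honesty="normal",
    )


def small_experiment_config(max_rounds: int = 5) -> ExperimentConfig:
    """Scaled-down study conditions used throughout the suite: 60-s
    sessions and trials, 30-evaluation class cap, 20-tree forests."""
    return ExperimentConfig(
        trial=TrialConfig(max_duration_s=60.0, class_count_cap=30, max_rounds=max_rounds),
        adversary=AdversaryConfig(n_candidates=8, probe_s=8.0),
        forest=ForestConfig(n_trees=20, seed=0),
        session_s=60.0,
    )


@pytest.fixture(scope="session")
def personal_forest(profile):
    """Baseline forest trained on one subject's normal sessions."""
    rng = np.random.default_rng(11)
    sit = gg.simulate_activity(profile, "sitting", 60, rng)
    walk = gg.simulate_activity(profile, "walking", 60, rng)
    return gg.train_forest(
        gg.extract_dataset([sit, walk]), ForestConfig(n_trees=20, seed=3)
    )


class StubClassifier:
    """Deterministic classifier emitting a fixed label pattern, cyclically."""

    classes_ = np.array(["sitting", "walking"], dtype=object)

    def __init__(self, pattern):
        self.pattern = list(pattern)
        self.trees_ = True  # quacks like a fitted forest
        self.n_trees = 1

    def predict_proba(self, X):
        n = X.shape[0]
        out = np.zeros((n, 2))
        for i in range(n):
            out[i, self.pattern[i % len(self.pattern)]] = 1.0
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
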