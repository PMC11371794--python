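"""Shared fixtures: small, fast synthetic cohorts with planted ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from cobci.core import EpochedRecording
from cobci.preprocess import crop_window
from cobci.simdata import SimConfig, generate_cohort


SMALL = dict(
    n_subjects=5,
    n_channels=8,
    sample_rate=250.0,
    n_sessions=2,
    n_blocks=2,
    n_sequences=6,
    images_per_sequence=50,
    targets_per_sequence=3,
)


def small_config(seed: int = 0, **overrides) -> SimConfig:
    kw = {**SMALL, **overrides, "seed": seed}
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-member, 2-session cohort at reduced scale (shared across tests)."""
    cohort, profiles = generate_cohort(small_config(seed=0))
    return cohort, profiles


@pytest.fixture(scope="session")
def analysis_block(small_cohort):
    """Session-1 block-1 epochs cropped to the analysis window."""
    cohort, _ = small_cohort
    return {m: crop_window(rec, 0.0, 500.0) for m, rec in cohort.block("sess1", "block1").items()}


def random_epochs(
    seed: int,
    n_trials: int = 40,
    n_channels: int = 4,
    n_samples: int = 25,
    n_targets: int | None = None,
    subject_id: str = "X",
) -> EpochedRecording:
    """Label-balanced random epochs (pure noise) for oracle-style unit tests."""
    rng = np.random.default_rng(seed)
    if n_targets is None:
        n_targets = max(1, n_trials // 5)
    labels = np.zeros(n_trials, dtype=np.int8)
    labels[:n_targets] = 1
    rng.shuffle(labels)
    sample_rate = 250.0
    return EpochedRecording(
        subject_id=subject_id,
        session_id="sess1",
        block_id="block1",
        data=rng.standard_normal((n_trials, n_channels, n_samples)),
        labels=labels,
        sample_rate=sample_rate,
        window_ms=(0.0, n_samples / sample_rate * 1000.0),
        channel_labels=[f"ch{i}" for i in range(n_channels)],
    )
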