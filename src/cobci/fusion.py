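"""Multi-user EEG fusion for centralized and distributed collaborative BCIs.

Centralized strategies combine the members' preprocessed signals before a
single classifier sees them:

* ``average_erp`` — element-wise mean across members (AE),
* ``parallel``    — channel-axis concatenation (PC, spatial domain),
* ``serial``      — time-axis concatenation (SC, temporal domain).

The distributed mode keeps one classifier per member and combines their
threshold-centered scores by weighted voting (:func:`weighted_vote`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochedRecording, ValidationError

__all__ = ["FusedEpochs", "fuse", "as_fused", "weighted_vote", "STRATEGIES"]

STRATEGIES = ("average_erp", "parallel", "serial")


@dataclass
class FusedEpochs:
    """Fused trial tensor ``(n_trials, n_channels', n_samples')`` with shared labels."""

    data: np.ndarray
    labels: np.ndarray
    member_ids: list[str]
    strategy: str
    sample_rate: float
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.data.ndim != 3:
            raise ValidationError("FusedEpochs.data must be 3-D")
        if len(self.labels) != self.data.shape[0]:
            raise ValidationError("FusedEpochs.labels length != trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def _check_pairing(epochs_list: list[EpochedRecording]) -> None:
    ref = epochs_list[0]
    for rec in epochs_list[1:]:
        if rec.n_trials != ref.n_trials:
            raise ValidationError(
                f"trial count mismatch: {rec.subject_id} has {rec.n_trials}, "
                f"{ref.subject_id} has {ref.n_trials}"
            )
        if not np.array_equal(rec.labels, ref.labels):
            raise ValidationError(
                f"label sequences differ between {ref.subject_id} and {rec.subject_id}; "
                "members must share one stimulus schedule"
            )
        if rec.n_samples != ref.n_samples:
            raise ValidationError("sample count mismatch between members")


def fuse(epochs_list: list[EpochedRecording], strategy: str = "average_erp") -> FusedEpochs:
    """Fuse members' epochs with one of the centralized strategies."""
    if not epochs_list:
        raise ValidationError("fuse() needs at least one recording")
    _check_pairing(epochs_list)
    ref = epochs_list[0]
    if strategy == "average_erp":
        for rec in epochs_list[1:]:
            if rec.n_channels != ref.n_channels:
                raise ValidationError("average_erp requires equal channel counts")
        data = np.mean([rec.data for rec in epochs_list], axis=0)
    elif strategy == "parallel":
        data = np.concatenate([rec.data for rec in epochs_list], axis=1)
    elif strategy == "serial":
        for rec in epochs_list[1:]:
            if rec.n_channels != ref.n_channels:
                raise ValidationError("serial combination requires equal channel counts")
        data = np.concatenate([rec.data for rec in epochs_list], axis=2)
    else:
        raise ValidationError(f"unknown fusion strategy {strategy!r}; choose from {STRATEGIES}")
    return FusedEpochs(
        data=data,
        labels=ref.labels.copy(),
        member_ids=[rec.subject_id for rec in epochs_list],
        strategy=strategy,
        sample_rate=ref.sample_rate,
        window_ms=ref.window_ms,
    )


def as_fused(epochs: EpochedRecording) -> FusedEpochs:
    """View a single member's epochs as a (trivially fused) tensor."""
    return fuse([epochs], "average_erp")


def weighted_vote(
    member_scores: list[np.ndarray],
    member_thresholds: list[float],
    weights: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Distributed fusion: weighted combination of threshold-centered member scores.

    ``combined_k = sum_i w_i (Z_{k,i} - Zth_i) / sum_i w_i``; the predicted
    label is 1 where ``combined_k > 0``.  Weights default to 1 (use each
    member's training AUC in practice).  Centered continuous scores (rather
    than hard votes) keep ROC analysis possible for the distributed mode.
    """
    if not member_scores:
        raise ValidationError("weighted_vote needs at least one member")
    scores = [np.asarray(s, dtype=float) for s in member_scores]
    n = scores[0].size
    for s in scores:
        if s.size != n:
            raise ValidationError("member score vectors must have equal length")
    if weights is None:
        weights = [1.0] * len(scores)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValidationError("weights must be >= 0")
    if w.sum() == 0:
        raise ValidationError("weights must not all be zero")
    centered = np.stack([s - th for s, th in zip(scores, member_thresholds)])
    combined = (w @ centered) / w.sum()
    return combined, (combined > 0).astype(np.int8)
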