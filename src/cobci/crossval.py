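"""Shared cross-validation conventions.

All training-stage validation in this package uses one convention: the
training block is split into five contiguous folds by trial order.  When the
trial count is a multiple of the sequence length (100 presentations per
sequence in the reference protocol, 1400 trials -> folds of
300/300/300/300/200), fold boundaries fall on sequence boundaries so every
fold keeps the 4-targets-per-100 class structure.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import EpochedRecording, ValidationError
from .classify import hdca_fit, hdca_score
from .fusion import FusedEpochs, fuse
from .metrics import auc

__all__ = ["contiguous_folds", "subset_trials", "subset_fused", "training_cv_auc"]


def contiguous_folds(n_trials: int, n_folds: int = 5, chunk_size: int = 100) -> list[np.ndarray]:
    """Contiguous fold index arrays; earlier folds take the larger share.

    If ``n_trials`` is a multiple of ``chunk_size`` the split respects
    chunk (sequence) boundaries; otherwise trials are split directly.
    """
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    if n_trials < n_folds:
        raise ValidationError(f"{n_trials} trials cannot form {n_folds} folds")
    if chunk_size > 1 and n_trials % chunk_size == 0 and n_trials // chunk_size >= n_folds:
        n_chunks = n_trials // chunk_size
        chunk_folds = np.array_split(np.arange(n_chunks), n_folds)
        return [
            np.concatenate([np.arange(c * chunk_size, (c + 1) * chunk_size) for c in cf])
            for cf in chunk_folds
        ]
    return [f for f in np.array_split(np.arange(n_trials), n_folds)]


def subset_trials(epochs: EpochedRecording, idx: np.ndarray) -> EpochedRecording:
    """A trial-subset view of an epoched recording (copies data)."""
    return EpochedRecording(
        subject_id=epochs.subject_id,
        session_id=epochs.session_id,
        block_id=epochs.block_id,
        data=epochs.data[idx],
        labels=epochs.labels[idx],
        sample_rate=epochs.sample_rate,
        window_ms=epochs.window_ms,
        channel_labels=list(epochs.channel_labels),
    )


def subset_fused(fused: FusedEpochs, idx: np.ndarray) -> FusedEpochs:
    return FusedEpochs(
        data=fused.data[idx],
        labels=fused.labels[idx],
        member_ids=list(fused.member_ids),
        strategy=fused.strategy,
        sample_rate=fused.sample_rate,
        window_ms=fused.window_ms,
    )


def training_cv_auc(
    epochs_list: list[EpochedRecording],
    strategy: str = "average_erp",
    n_folds: int = 5,
    chunk_size: int = 100,
    window_count: int = 5,
) -> float:
    """Mean held-out-fold AUC of an HDCA model on fused member epochs.

    Folds whose held-out trials lack one class are skipped (with a warning);
    at least one usable fold is required.
    """
    fused = fuse(epochs_list, strategy)
    folds = contiguous_folds(fused.n_trials, n_folds, chunk_size)
    all_idx = np.arange(fused.n_trials)
    aucs = []
    for fold in folds:
        train_idx = np.setdiff1d(all_idx, fold)
        test = subset_fused(fused, fold)
        if not ((test.labels == 0).any() and (test.labels == 1).any()):
            warnings.warn("skipping CV fold with a single class", stacklevel=2)
            continue
        model = hdca_fit(subset_fused(fused, train_idx), window_count=window_count)
        sv = hdca_score(model, test)
        aucs.append(auc(sv.scores, test.labels))
    if not aucs:
        raise ValidationError("no CV fold contained both classes")
    return float(np.mean(aucs))
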