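"""Single-trial ERP classification (HDCA) and Euclidean-space alignment (EA).

HDCA — hierarchical discriminant component analysis — splits each trial into
``W`` non-overlapping time windows, learns one spatial Fisher linear
discriminant per window (treating every sample in the window as an
observation), reduces each window to one spatially projected feature per
trial, and learns a temporal FLD over the ``W`` window features.  The final
score ``Z_k`` is thresholded at the midpoint of the class-template
projections; by construction target trials score high.

EA whitens each recording domain (session/block set) by the inverse square
root of its mean trial covariance so that every domain's mean covariance
becomes the identity — removing the linear covariance shift between sessions
without using any labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .core import ValidationError
from .fusion import FusedEpochs

__all__ = [
    "HDCAModel",
    "ScoreVector",
    "EAReference",
    "hdca_fit",
    "hdca_score",
    "ea_reference",
    "ea_align",
    "ea_hdca",
]

_SCATTER_RIDGE = 1e-6


@dataclass
class HDCAModel:
    """Fitted HDCA classifier.

    ``spatial_filters`` is ``(W, n_channels)`` (one FLD direction per window),
    ``temporal_weights`` is the ``W``-vector combining window features, and
    ``threshold`` is the midpoint of the projected class templates.
    """

    window_count: int
    window_samples: int
    spatial_filters: np.ndarray
    temporal_weights: np.ndarray
    threshold: float
    template_projection_0: np.ndarray  # diagnostics: class templates in window-feature space
    template_projection_1: np.ndarray

    def __post_init__(self) -> None:
        if self.window_count < 1:
            raise ValidationError("window_count must be >= 1")
        if not np.all(np.isfinite(self.spatial_filters)) or not np.all(np.isfinite(self.temporal_weights)):
            raise ValidationError("HDCA weights must be finite")


@dataclass
class ScoreVector:
    """Per-trial continuous scores with the model's decision threshold."""

    scores: np.ndarray
    threshold: float

    @property
    def labels(self) -> np.ndarray:
        return (self.scores > self.threshold).astype(np.int8)


@dataclass
class EAReference:
    """Mean trial covariance of a domain and its symmetric inverse square root."""

    mean_cov: np.ndarray
    inv_sqrt: np.ndarray
    n_trials: int


def _fld_direction(rows0: np.ndarray, rows1: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fisher direction ``S_W^-1 (mean0 - mean1)`` with a ridge on the scatter.

    Returns (direction, mean0, mean1); the caller fixes the sign.
    """
    m0 = rows0.mean(axis=0)
    m1 = rows1.mean(axis=0)
    c0 = rows0 - m0
    c1 = rows1 - m1
    sw = c0.T @ c0 + c1.T @ c1
    dim = sw.shape[0]
    ridge = _SCATTER_RIDGE * np.trace(sw) / dim
    if ridge <= 0:
        ridge = _SCATTER_RIDGE
    sw = sw + ridge * np.eye(dim)
    try:
        u = scipy.linalg.solve(sw, m0 - m1, assume_a="pos")
    except scipy.linalg.LinAlgError:  # pragma: no cover - ridge makes this rare
        u = np.linalg.pinv(sw) @ (m0 - m1)
    return u, m0, m1


def _window_features(data: np.ndarray, spatial_filters: np.ndarray, window_samples: int) -> np.ndarray:
    """Per-trial window features: mean over the window of the spatially projected samples.

    ``data`` is (n_trials, n_channels, n_samples); returns (n_trials, W).
    """
    n_trials, _, n_samples = data.shape
    w_count = spatial_filters.shape[0]
    feats = np.empty((n_trials, w_count))
    for w in range(w_count):
        seg = data[:, :, w * window_samples : (w + 1) * window_samples]
        feats[:, w] = np.einsum("c,kcs->k", spatial_filters[w], seg) / window_samples
    return feats


def hdca_fit(fused: FusedEpochs, window_count: int = 5) -> HDCAModel:
    """Fit HDCA on fused (or single-subject) epochs.

    The sample count must divide evenly into ``window_count`` windows (with a
    [0, 500) ms analysis window at 250 Hz: 125 samples, 5 windows of 25).
    """
    labels = fused.labels
    if not ((labels == 0).any() and (labels == 1).any()):
        missing = "target" if not (labels == 1).any() else "non-target"
        raise ValidationError(f"hdca_fit: {missing} class absent from training data")
    n_samples = fused.n_samples
    if n_samples % window_count != 0:
        raise ValidationError(
            f"{n_samples} samples not divisible into {window_count} windows"
        )
    nw = n_samples // window_count
    data = np.asarray(fused.data, dtype=float)
    idx0 = labels == 0
    idx1 = labels == 1

    filters = np.empty((window_count, fused.n_channels))
    for w in range(window_count):
        seg = data[:, :, w * nw : (w + 1) * nw]
        # every sample in the window is an observation: (n_trials*nw, n_channels)
        rows0 = seg[idx0].transpose(0, 2, 1).reshape(-1, fused.n_channels)
        rows1 = seg[idx1].transpose(0, 2, 1).reshape(-1, fused.n_channels)
        u, _, _ = _fld_direction(rows0, rows1)
        filters[w] = u
    # sign convention: target-class mean window feature >= non-target mean
    feats = _window_features(data, filters, nw)
    flip = feats[idx1].mean(axis=0) < feats[idx0].mean(axis=0)
    filters[flip] *= -1.0
    feats[:, flip] *= -1.0

    v, p0, p1 = _fld_direction(feats[idx0], feats[idx1])
    if (p1 - p0) @ v < 0:
        v = -v
    threshold = float(0.5 * (p0 + p1) @ v)
    return HDCAModel(
        window_count=window_count,
        window_samples=nw,
        spatial_filters=filters,
        temporal_weights=v,
        threshold=threshold,
        template_projection_0=p0,
        template_projection_1=p1,
    )


def hdca_score(model: HDCAModel, fused: FusedEpochs) -> ScoreVector:
    """Score trials with a fitted model: ``Z_k = y_k . v`` over window features."""
    if fused.n_channels != model.spatial_filters.shape[1]:
        raise ValidationError(
            f"channel count {fused.n_channels} != model's {model.spatial_filters.shape[1]}"
        )
    if fused.n_samples != model.window_count * model.window_samples:
        raise ValidationError(
            f"sample count {fused.n_samples} != model's "
            f"{model.window_count} x {model.window_samples}"
        )
    feats = _window_features(np.asarray(fused.data, dtype=float), model.spatial_filters, model.window_samples)
    return ScoreVector(scores=feats @ model.temporal_weights, threshold=model.threshold)


# ---------------------------------------------------------------------------
# Euclidean-space alignment
# ---------------------------------------------------------------------------

def ea_reference(fused: FusedEpochs) -> EAReference:
    """Mean trial covariance of a domain (labels unused) and its inverse square root."""
    if fused.n_trials < 1:
        raise ValidationError("ea_reference needs at least one trial")
    data = np.asarray(fused.data, dtype=float)
    r = np.einsum("kcs,kds->cd", data, data) / fused.n_trials
    if not np.any(r):
        raise ValidationError("degenerate (all-zero) covariance; cannot align")
    r = 0.5 * (r + r.T)
    vals, vecs = np.linalg.eigh(r)
    # pseudo-inverse square root: directions with (numerically) zero variance
    # (e.g. the channel-mean direction after common-average referencing) carry
    # no data and are left untouched rather than amplified
    keep = vals > 1e-10 * vals.max()
    inv_vals = np.where(keep, 1.0 / np.sqrt(np.maximum(vals, 1e-300)), 0.0)
    inv_sqrt = (vecs * inv_vals) @ vecs.T
    return EAReference(mean_cov=r, inv_sqrt=inv_sqrt, n_trials=fused.n_trials)


def ea_align(fused: FusedEpochs, reference: EAReference) -> FusedEpochs:
    """Whiten every trial by the reference: ``X~_k = R^{-1/2} X_k``.

    When the reference comes from the same trials, the aligned mean trial
    covariance equals the identity.
    """
    if reference.inv_sqrt.shape[0] != fused.n_channels:
        raise ValidationError("reference channel dimension does not match data")
    data = np.einsum("cd,kds->kcs", reference.inv_sqrt, np.asarray(fused.data, dtype=float))
    return replace(fused, data=data)


def ea_hdca(train_fused: FusedEpochs, test_fused: FusedEpochs, window_count: int = 5) -> ScoreVector:
    """Cross-domain HDCA: align each domain with its own (label-free) reference,
    fit on aligned training data, score aligned test data."""
    if train_fused.n_channels != test_fused.n_channels:
        raise ValidationError("train/test channel counts differ")
    train_aligned = ea_align(train_fused, ea_reference(train_fused))
    test_aligned = ea_align(test_fused, ea_reference(test_fused))
    model = hdca_fit(train_aligned, window_count=window_count)
    return hdca_score(model, test_aligned)
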