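"""Individual and collaborative capability scoring (MIMC) and mu optimization.

A member's *individual capability* is the signal to signal-plus-noise ratio
(SSNR) attained by the leading xDAWN spatial filter: the largest generalized
eigenvalue of the pair (target-template covariance, total data covariance) in
channel space.  The *collaborative capability* between two members is the mean
Pearson correlation of their flattened single-trial target responses.  The
MIMC score weights the two (z-scored across candidates) by ``mu``:

    M = mu * z(M_in) + (1 - mu) * z(M_co)

``mu`` itself is chosen by five-fold cross-validation on the training block:
for each candidate value, every member is paired with its argmax-M candidate,
the pair is fused by ERP averaging, and an HDCA model trained on the other
folds is scored on the held-out fold; the mu with the best mean AUC wins
(ties go to the smallest mu).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.linalg

from .core import EpochedRecording, ValidationError
from .classify import hdca_fit, hdca_score
from .crossval import contiguous_folds, subset_fused, subset_trials
from .fusion import FusedEpochs, fuse
from .metrics import auc

__all__ = [
    "ClassTemplates",
    "XdawnResult",
    "CapabilityScores",
    "class_templates",
    "xdawn_ssnr",
    "collaborative_capability",
    "zscore",
    "mimc_scores",
    "mu_grid",
    "select_mu",
    "optimize_mu",
]

_XDAWN_RIDGE = 1e-9


@dataclass
class ClassTemplates:
    """Per-class mean epochs (channels x samples) with their trial counts."""

    p0: np.ndarray
    p1: np.ndarray
    n0: int
    n1: int


@dataclass
class XdawnResult:
    """Leading xDAWN filter and its SSNR (the largest generalized eigenvalue)."""

    filter: np.ndarray
    ssnr: float
    signal_cov: np.ndarray
    total_cov: np.ndarray

    def __post_init__(self) -> None:
        if self.ssnr < 0:
            raise ValidationError("SSNR must be >= 0")


@dataclass
class CapabilityScores:
    """MIMC capability table for one predefined user against its candidates."""

    user_id: str
    candidate_ids: list[str]
    m_in: np.ndarray
    m_co: np.ndarray
    mu: float
    m: np.ndarray

    @property
    def best_candidate(self) -> str:
        # ties resolve to the lowest candidate index (candidate order = member order)
        return self.candidate_ids[int(np.argmax(self.m))]


def class_templates(epochs: EpochedRecording | FusedEpochs) -> ClassTemplates:
    """Arithmetic-mean class templates; both classes must be present."""
    labels = np.asarray(epochs.labels)
    data = np.asarray(epochs.data, dtype=float)
    for j in (0, 1):
        if not (labels == j).any():
            name = "non-target" if j == 0 else "target"
            raise ValidationError(f"class_templates: no {name} trials")
    return ClassTemplates(
        p0=data[labels == 0].mean(axis=0),
        p1=data[labels == 1].mean(axis=0),
        n0=int((labels == 0).sum()),
        n1=int((labels == 1).sum()),
    )


def xdawn_ssnr(epochs: EpochedRecording | FusedEpochs) -> XdawnResult:
    """Leading xDAWN SSNR: largest eigenvalue of (P1 P1^T, sum_k X_k X_k^T).

    Covariances are formed in channel space (so the quadratic forms of the
    Rayleigh quotient are well defined); a small ridge proportional to the
    mean channel variance keeps the total covariance invertible when the
    channel count exceeds the effective trial rank.
    """
    labels = np.asarray(epochs.labels)
    data = np.asarray(epochs.data, dtype=float)
    if not (labels == 1).any():
        raise ValidationError("xdawn_ssnr: no target trials")
    p1 = data[labels == 1].mean(axis=0)
    signal_cov = p1 @ p1.T
    total_cov = np.einsum("kcs,kds->cd", data, data)
    n_c = total_cov.shape[0]
    ridge = _XDAWN_RIDGE * np.trace(total_cov) / n_c
    total_reg = total_cov + ridge * np.eye(n_c)
    if not np.all(np.isfinite(total_reg)) or not np.all(np.isfinite(signal_cov)):
        raise ValidationError("xdawn_ssnr: non-finite covariance")
    # solve on the support of the total covariance: rank-deficient directions
    # (e.g. the channel-mean direction zeroed by common-average referencing)
    # carry no signal but would otherwise dominate the eigenvector through the
    # near-zero denominator
    try:
        tvals, tvecs = scipy.linalg.eigh(total_reg)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - eigh on sym matrix
        raise ValidationError(f"xdawn_ssnr: eigendecomposition failed: {exc}") from exc
    keep = tvals > 1e-9 * tvals.max()
    if not keep.any():
        raise ValidationError(
            f"xdawn_ssnr: total covariance numerically zero "
            f"(cond={np.linalg.cond(total_reg):.3g})"
        )
    whiten = tvecs[:, keep] / np.sqrt(tvals[keep])
    vals, vecs = scipy.linalg.eigh(whiten.T @ signal_cov @ whiten)
    u = whiten @ vecs[:, -1]
    u = u / np.linalg.norm(u)
    # report the Rayleigh quotient at the returned filter (== largest eigenvalue)
    ssnr = float((u @ signal_cov @ u) / (u @ total_reg @ u))
    return XdawnResult(filter=u, ssnr=max(ssnr, 0.0), signal_cov=signal_cov, total_cov=total_reg)


def collaborative_capability(
    user_epochs: EpochedRecording | FusedEpochs,
    cand_epochs: EpochedRecording | FusedEpochs,
) -> float:
    """Mean Pearson correlation of the two members' flattened target trials.

    Symmetric in its arguments; a zero-variance trial contributes 0 (warned).
    """
    lu = np.asarray(user_epochs.labels)
    lc = np.asarray(cand_epochs.labels)
    du = np.asarray(user_epochs.data, dtype=float)
    dc = np.asarray(cand_epochs.data, dtype=float)
    if du.shape != dc.shape or not np.array_equal(lu, lc):
        raise ValidationError(
            "collaborative_capability: trials must be paired (equal shapes and label sequences)"
        )
    if not (lu == 1).any():
        raise ValidationError("collaborative_capability: no target trials")
    tu = du[lu == 1].reshape((lu == 1).sum(), -1)
    tc = dc[lu == 1].reshape((lu == 1).sum(), -1)
    tu = tu - tu.mean(axis=1, keepdims=True)
    tc = tc - tc.mean(axis=1, keepdims=True)
    nu = np.linalg.norm(tu, axis=1)
    nc = np.linalg.norm(tc, axis=1)
    bad = (nu == 0) | (nc == 0)
    if bad.any():
        warnings.warn(
            f"{bad.sum()} zero-variance target trial(s); their correlation is defined as 0",
            stacklevel=2,
        )
    denom = np.where(bad, 1.0, nu * nc)
    corr = np.where(bad, 0.0, np.einsum("kf,kf->k", tu, tc) / denom)
    return float(corr.mean())


def zscore(x: np.ndarray) -> np.ndarray:
    """Population z-score; an all-equal vector maps to zeros (with a warning)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()  # population form (divide by N)
    if sd == 0:
        warnings.warn("zero spread in capability vector; z-scores set to 0", stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def mimc_scores(
    user_id: str,
    block: Mapping[str, EpochedRecording],
    mu: float,
    *,
    ssnr_table: Mapping[str, float] | None = None,
) -> CapabilityScores:
    """MIMC capability table for ``user_id`` against every other block member.

    ``ssnr_table`` may carry precomputed per-member SSNRs (they do not depend
    on the predefined user).
    """
    if not 0.0 <= mu <= 1.0:
        raise ValidationError(f"mu must be in [0, 1], got {mu}")
    candidates = [m for m in block if m != user_id]
    if user_id not in block:
        raise ValidationError(f"unknown user {user_id!r}")
    if len(candidates) < 2:
        raise ValidationError("MIMC needs at least 2 candidates (z-scores need spread)")
    user_epochs = block[user_id]
    m_in = np.array(
        [
            ssnr_table[c] if ssnr_table is not None else xdawn_ssnr(block[c]).ssnr
            for c in candidates
        ]
    )
    m_co = np.array([collaborative_capability(user_epochs, block[c]) for c in candidates])
    m = mu * zscore(m_in) + (1.0 - mu) * zscore(m_co)
    return CapabilityScores(
        user_id=user_id, candidate_ids=candidates, m_in=m_in, m_co=m_co, mu=float(mu), m=m
    )


# ---------------------------------------------------------------------------
# mu optimization
# ---------------------------------------------------------------------------

def mu_grid(grid_step: float = 0.01) -> np.ndarray:
    """The candidate grid {0, step, 2*step, ..., 1}."""
    if not 0 < grid_step <= 1:
        raise ValidationError("grid_step must be in (0, 1]")
    return np.round(np.arange(0.0, 1.0 + grid_step / 2.0, grid_step), 10)


def select_mu(score_table: pd.DataFrame) -> float:
    """Argmax of the fold-mean score; ties resolve to the smallest mu."""
    means = score_table.groupby("mu")["score"].mean().sort_index()
    return float(means.index[int(np.argmax(means.to_numpy()))])


def optimize_mu(
    block: Mapping[str, EpochedRecording],
    grid_step: float = 0.01,
    n_folds: int = 5,
    chunk_size: int = 100,
    window_count: int = 5,
) -> tuple[float, pd.DataFrame]:
    """Cross-validated choice of the individual/collaborative weight ``mu``.

    For each fold, capabilities are computed on the training folds only; the
    held-out fold is scored by an HDCA model trained on the training folds'
    argmax-M pairs (average-ERP fusion).  Returns the winning mu and the full
    (mu, fold, score) table.
    """
    members = list(block)
    if len(members) < 3:
        raise ValidationError("optimize_mu needs at least 3 members (2 candidates per user)")
    grid = mu_grid(grid_step)
    ref = block[members[0]]
    folds = contiguous_folds(ref.n_trials, n_folds, chunk_size)
    all_idx = np.arange(ref.n_trials)

    records = []
    for f, fold in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, fold)
        train = {m: subset_trials(block[m], train_idx) for m in members}
        test = {m: subset_trials(block[m], fold) for m in members}
        if not ((test[members[0]].labels == 1).any() and (test[members[0]].labels == 0).any()):
            warnings.warn(f"fold {f} lacks a class; skipped", stacklevel=2)
            continue
        ssnr_tab = {m: xdawn_ssnr(train[m]).ssnr for m in members}
        # per-user z-scored capabilities (independent of mu)
        z_in: dict[str, np.ndarray] = {}
        z_co: dict[str, np.ndarray] = {}
        cand_ids: dict[str, list[str]] = {}
        for user in members:
            cands = [m for m in members if m != user]
            cand_ids[user] = cands
            z_in[user] = zscore(np.array([ssnr_tab[c] for c in cands]))
            z_co[user] = zscore(
                np.array([collaborative_capability(train[user], train[c]) for c in cands])
            )
        pair_auc: dict[tuple[str, str], float] = {}
        pairing_score: dict[tuple[str, ...], float] = {}
        for mu in grid:
            pairing = tuple(
                cand_ids[user][int(np.argmax(mu * z_in[user] + (1.0 - mu) * z_co[user]))]
                for user in members
            )
            if pairing not in pairing_score:
                aucs = []
                for user, cand in zip(members, pairing):
                    key = (user, cand) if user < cand else (cand, user)
                    if key not in pair_auc:
                        fused_train = fuse([train[key[0]], train[key[1]]], "average_erp")
                        fused_test = fuse([test[key[0]], test[key[1]]], "average_erp")
                        model = hdca_fit(fused_train, window_count=window_count)
                        sv = hdca_score(model, fused_test)
                        pair_auc[key] = auc(sv.scores, fused_test.labels)
                    aucs.append(pair_auc[key])
                pairing_score[pairing] = float(np.mean(aucs))
            records.append({"mu": float(mu), "fold": f, "score": pairing_score[pairing]})
    if not records:
        raise ValidationError("no usable folds for mu optimization")
    table = pd.DataFrame.from_records(records)
    return select_mu(table), table
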