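"""Experiment protocols and reporting for group-mode comparisons.

The evaluation convention: all selection and training (mu, capabilities,
matching, HDCA, thresholds, alignment references for the training side) use
block 1 of the training session only; blocks 2 and 3 of the test session form
the test set.  Within-session runs use plain HDCA; cross-session runs use
EA-HDCA (each domain whitened by its own label-free covariance reference).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CohortIndex, EpochedRecording, ValidationError
from .capability import optimize_mu
from .classify import ea_hdca, hdca_fit, hdca_score
from .fusion import FusedEpochs, fuse
from .grouping import match_all, sffs_subgroup
from .metrics import auc, binary_metrics
from .preprocess import crop_window

__all__ = ["EvalReport", "run_protocol", "random_group_curve", "GROUPING_SPECS"]

GROUPING_SPECS = (
    "single",
    "fixed",
    "random",
    "mimc",
    "matched",
    "ipd",
    "bip",
    "bcp",
    "sffs",
    "all_member",
)


@dataclass
class EvalReport:
    """Per-group metrics plus aggregates and full provenance."""

    rows: pd.DataFrame  # columns: user, group, auc, tpr, fpr
    aggregate: dict
    protocol: dict
    config_hash: str
    seed: int | None
    per_trial_scores: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = self.rows["auc"].to_numpy()
        if ((a < 0) | (a > 1)).any():
            raise ValidationError("AUC out of [0, 1]")

    def summary(self) -> str:
        agg = self.aggregate
        lines = [
            f"protocol: {self.protocol['mode']} "
            f"{self.protocol['train_session']}->{self.protocol['test_session']}, "
            f"grouping={self.protocol['grouping']}",
            f"groups: {len(self.rows)}",
            f"AUC  mean (sd): {agg['auc_mean']:.4f} ({agg['auc_sd']:.4f})",
            f"TPR  mean (sd): {agg['tpr_mean']:.4f} ({agg['tpr_sd']:.4f})",
            f"FPR  mean (sd): {agg['fpr_mean']:.4f} ({agg['fpr_sd']:.4f})",
        ]
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _crop(epochs: EpochedRecording, window: tuple[float, float] | None) -> EpochedRecording:
    if window is None or tuple(epochs.window_ms) == tuple(window):
        return epochs
    return crop_window(epochs, *window)


def _concat_fused(parts: list[FusedEpochs]) -> FusedEpochs:
    ref = parts[0]
    return FusedEpochs(
        data=np.concatenate([p.data for p in parts], axis=0),
        labels=np.concatenate([p.labels for p in parts]),
        member_ids=list(ref.member_ids),
        strategy=ref.strategy,
        sample_rate=ref.sample_rate,
        window_ms=ref.window_ms,
    )


def _group_fused(
    blocks: list[Mapping[str, EpochedRecording]],
    group: list[str],
    strategy: str,
    window: tuple[float, float] | None,
) -> FusedEpochs:
    parts = [fuse([_crop(blk[m], window) for m in group], strategy) for blk in blocks]
    return _concat_fused(parts)


def _evaluate_group(
    train_fused: FusedEpochs,
    test_fused: FusedEpochs,
    mode: str,
    window_count: int,
) -> tuple[float, float, float, np.ndarray]:
    if mode == "cross":
        sv = ea_hdca(train_fused, test_fused, window_count=window_count)
    else:
        model = hdca_fit(train_fused, window_count=window_count)
        sv = hdca_score(model, test_fused)
    a = auc(sv.scores, test_fused.labels)
    tpr, fpr = binary_metrics(test_fused.labels, sv.labels)
    return a, tpr, fpr, sv.scores


def run_protocol(
    cohort: CohortIndex,
    mode: str = "within",
    grouping_spec: str = "mimc",
    fusion_strategy: str = "average_erp",
    train_session: str | None = None,
    test_session: str | None = None,
    mu: float | str = 0.5,
    mu_grid_step: float = 0.1,
    seed: int | None = 0,
    window_count: int = 5,
    analysis_window_ms: tuple[float, float] | None = (0.0, 500.0),
    n_folds: int = 5,
    chunk_size: int = 100,
) -> EvalReport:
    """Run one group-mode evaluation protocol over a cohort.

    ``mode`` is ``"within"`` (train and test sessions equal, plain HDCA) or
    ``"cross"`` (EA-HDCA).  ``mu`` may be a number or ``"optimize"`` to run
    the cross-validated grid search on the training block.  The ``matched``
    grouping enumerates candidates and reports each user's best *test* AUC
    pair — a non-deployable oracle ceiling, flagged in the report notes.
    """
    if mode not in ("within", "cross"):
        raise ValidationError(f"mode must be 'within' or 'cross', got {mode!r}")
    if grouping_spec not in GROUPING_SPECS:
        raise ValidationError(f"unknown grouping {grouping_spec!r}; choose from {GROUPING_SPECS}")
    sessions = cohort.sessions
    if train_session is None:
        train_session = sessions[0]
    if test_session is None:
        test_session = train_session if mode == "within" else sessions[-1]
    blocks = cohort.blocks
    if len(blocks) < 2:
        raise ValidationError("protocol needs a training block and at least one test block")
    train_block_id, test_block_ids = blocks[0], blocks[1:]

    train_raw = cohort.block(train_session, train_block_id)
    train = {m: _crop(rec, analysis_window_ms) for m, rec in train_raw.items()}
    test_blocks = [
        {m: rec for m, rec in cohort.block(test_session, b).items()} for b in test_block_ids
    ]
    members = cohort.members

    notes: list[str] = []
    if mu == "optimize":
        mu_value, _ = optimize_mu(train, grid_step=mu_grid_step, n_folds=n_folds, chunk_size=chunk_size, window_count=window_count)
        notes.append(f"mu optimized on training block: {mu_value}")
    else:
        mu_value = float(mu)

    # --- group definitions (training data only) ---
    groups: list[tuple[str, list[str]]] = []
    if grouping_spec == "single":
        groups = [(m, [m]) for m in members]
    elif grouping_spec == "fixed":
        if len(members) % 2:
            raise ValidationError("fixed grouping needs an even member count")
        for i in range(0, len(members), 2):
            a, b = members[i], members[i + 1]
            groups += [(a, [a, b]), (b, [b, a])]
    elif grouping_spec in ("random", "mimc", "ipd", "bip", "bcp"):
        assignments = match_all(
            train, strategy=grouping_spec, mu=mu_value, seed=seed,
            n_folds=n_folds, chunk_size=chunk_size, window_count=window_count,
        )
        groups = [(a.user_id, [a.user_id, a.collaborator_id]) for a in assignments]
    elif grouping_spec == "sffs":
        sub = sffs_subgroup(
            train, mu=mu_value, n_folds=n_folds, chunk_size=chunk_size, window_count=window_count
        )
        groups = [("+".join(sub.members), list(sub.members))]
        notes.append(f"sffs subgroup size {len(sub.members)}")
    elif grouping_spec == "all_member":
        groups = [("+".join(members), list(members))]
    elif grouping_spec == "matched":
        notes.append("matched grouping is a test-set oracle ceiling; not deployable")

    rows = []
    per_trial: dict[str, np.ndarray] = {}
    if grouping_spec == "matched":
        for user in members:
            best = None
            for cand in members:
                if cand == user:
                    continue
                tr = _group_fused([train], [user, cand], fusion_strategy, None)
                te = _group_fused(test_blocks, [user, cand], fusion_strategy, analysis_window_ms)
                a, tpr, fpr, scores = _evaluate_group(tr, te, mode, window_count)
                if best is None or a > best[0]:
                    best = (a, tpr, fpr, scores, cand)
            a, tpr, fpr, scores, cand = best
            rows.append({"user": user, "group": f"{user}+{cand}", "auc": a, "tpr": tpr, "fpr": fpr})
            per_trial[user] = scores
    else:
        for user, group in groups:
            tr = _group_fused([train], group, fusion_strategy, None)
            te = _group_fused(test_blocks, group, fusion_strategy, analysis_window_ms)
            a, tpr, fpr, scores = _evaluate_group(tr, te, mode, window_count)
            rows.append({"user": user, "group": "+".join(group), "auc": a, "tpr": tpr, "fpr": fpr})
            per_trial[user] = scores

    df = pd.DataFrame.from_records(rows)
    aggregate = {
        "auc_mean": float(df["auc"].mean()),
        "auc_sd": float(df["auc"].std(ddof=0)),
        "tpr_mean": float(df["tpr"].mean()),
        "tpr_sd": float(df["tpr"].std(ddof=0)),
        "fpr_mean": float(df["fpr"].mean()),
        "fpr_sd": float(df["fpr"].std(ddof=0)),
    }
    protocol = {
        "mode": mode,
        "grouping": grouping_spec,
        "fusion": fusion_strategy,
        "train_session": train_session,
        "train_block": train_block_id,
        "test_session": test_session,
        "test_blocks": list(test_block_ids),
        "mu": mu_value,
        "window_count": window_count,
        "analysis_window_ms": analysis_window_ms,
    }
    return EvalReport(
        rows=df,
        aggregate=aggregate,
        protocol=protocol,
        config_hash=_config_hash({**protocol, "seed": seed, "members": members}),
        seed=seed,
        per_trial_scores=per_trial,
        notes=notes,
    )


def random_group_curve(
    cohort: CohortIndex,
    sizes: list[int],
    n_draws: int = 100,
    mode: str = "within",
    fusion_strategy: str = "average_erp",
    train_session: str | None = None,
    test_session: str | None = None,
    seed: int = 0,
    window_count: int = 5,
    analysis_window_ms: tuple[float, float] | None = (0.0, 500.0),
) -> pd.DataFrame:
    """Mean test AUC of randomly drawn groups as a function of group size.

    For each size ``n``, up to ``n_draws`` distinct member subsets are drawn
    (enumeration is capped, matching the convention of sampling at most 100
    random combinations per size).
    """
    sessions = cohort.sessions
    if train_session is None:
        train_session = sessions[0]
    if test_session is None:
        test_session = train_session if mode == "within" else sessions[-1]
    blocks = cohort.blocks
    train = {
        m: _crop(rec, analysis_window_ms)
        for m, rec in cohort.block(train_session, blocks[0]).items()
    }
    test_blocks = [cohort.block(test_session, b) for b in blocks[1:]]
    members = cohort.members
    rng = np.random.default_rng(seed)
    records = []
    for size in sizes:
        if size > len(members):
            raise ValidationError(f"group size {size} exceeds cohort size {len(members)}")
        seen: set[tuple[str, ...]] = set()
        attempts = 0
        while len(seen) < n_draws and attempts < 50 * n_draws:
            attempts += 1
            group = tuple(sorted(rng.choice(members, size=size, replace=False).tolist()))
            if group in seen:
                continue
            seen.add(group)
            tr = _group_fused([train], list(group), fusion_strategy, None)
            te = _group_fused(test_blocks, list(group), fusion_strategy, analysis_window_ms)
            a, tpr, fpr, _ = _evaluate_group(tr, te, mode, window_count)
            records.append({"size": size, "group": "+".join(group), "auc": a, "tpr": tpr, "fpr": fpr})
    return pd.DataFrame.from_records(records)
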