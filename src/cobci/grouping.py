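"""Group-member selection: two-user matching strategies and SFFS subgroup search.

Matching strategies
-------------------
* ``mimc``   — argmax of the MIMC capability score (individual SSNR +
  target-ERP correlation, weighted by mu).
* ``random`` — uniform draw among candidates (the conventional baseline).
* ``ipd``    — individual performance dissimilarity: the candidate whose
  single-subject training-CV AUC is closest to the user's.
* ``bip``    — best individual performance: highest single-subject AUC.
* ``bcp``    — best collaborative performance: highest fused-pair training-CV
  AUC (average-ERP fusion + HDCA).

Ties everywhere resolve to the lowest member index, so results are
deterministic given the seed and configuration.

Subgroup selection runs sequential forward floating selection (SFFS) with the
MIMC score as inclusion/exclusion objective: the current subgroup's
average-ERP fusion is treated as the predefined user, candidates compete by
MIMC score, and a conditional exclusion step removes the weakest member when
doing so improves the subgroup's cross-validated AUC.  The search stops when
an accepted step no longer improves CV AUC by more than ``epsilon``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import EpochedRecording, ValidationError
from .capability import (
    collaborative_capability,
    mimc_scores,
    xdawn_ssnr,
    zscore,
)
from .crossval import training_cv_auc
from .fusion import fuse

__all__ = ["PairAssignment", "Subgroup", "MATCH_STRATEGIES", "match", "match_all", "sffs_subgroup"]

MATCH_STRATEGIES = ("mimc", "random", "ipd", "bip", "bcp")


@dataclass(frozen=True)
class PairAssignment:
    user_id: str
    collaborator_id: str
    strategy: str
    score: float

    def __post_init__(self) -> None:
        if self.user_id == self.collaborator_id:
            raise ValidationError("user cannot collaborate with itself")


@dataclass
class Subgroup:
    """An ordered selected member set with its full selection trace."""

    members: list[str]
    trace: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError("subgroup members must be unique")
        if not self.members:
            raise ValidationError("subgroup must contain at least one member")


def _single_aucs(
    block: Mapping[str, EpochedRecording], n_folds: int, chunk_size: int, window_count: int
) -> dict[str, float]:
    return {
        m: training_cv_auc([block[m]], "average_erp", n_folds, chunk_size, window_count)
        for m in block
    }


def _match_one(
    block: Mapping[str, EpochedRecording],
    user: str,
    strategy: str,
    mu: float,
    rng: np.random.Generator | None,
    n_folds: int,
    chunk_size: int,
    window_count: int,
    single_aucs: dict[str, float] | None = None,
    ssnr_table: dict[str, float] | None = None,
) -> PairAssignment:
    candidates = [m for m in block if m != user]
    if not candidates:
        raise ValidationError("no candidate collaborators")
    if strategy not in MATCH_STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}; choose from {MATCH_STRATEGIES}")
    if len(candidates) == 1:
        # degenerate 2-member cohort: the single candidate is the match
        return PairAssignment(user, candidates[0], strategy, float("nan"))
    if strategy == "mimc":
        scores = mimc_scores(user, block, mu, ssnr_table=ssnr_table)
        i = int(np.argmax(scores.m))
        return PairAssignment(user, scores.candidate_ids[i], "mimc", float(scores.m[i]))
    if strategy == "random":
        if rng is None:
            raise ValidationError("random matching needs a seed")
        cand = candidates[int(rng.integers(0, len(candidates)))]
        return PairAssignment(user, cand, "random", float("nan"))
    if strategy in ("ipd", "bip"):
        if single_aucs is None:
            single_aucs = _single_aucs(block, n_folds, chunk_size, window_count)
        if strategy == "ipd":
            dis = np.array([abs(single_aucs[c] - single_aucs[user]) for c in candidates])
            i = int(np.argmin(dis))
            return PairAssignment(user, candidates[i], "ipd", float(dis[i]))
        vals = np.array([single_aucs[c] for c in candidates])
        i = int(np.argmax(vals))
        return PairAssignment(user, candidates[i], "bip", float(vals[i]))
    if strategy == "bcp":
        vals = np.array(
            [
                training_cv_auc([block[user], block[c]], "average_erp", n_folds, chunk_size, window_count)
                for c in candidates
            ]
        )
        i = int(np.argmax(vals))
        return PairAssignment(user, candidates[i], "bcp", float(vals[i]))
    raise ValidationError(f"unknown strategy {strategy!r}; choose from {MATCH_STRATEGIES}")


def match(
    block: Mapping[str, EpochedRecording],
    user: str,
    strategy: str = "mimc",
    mu: float = 0.5,
    seed: int | None = None,
    n_folds: int = 5,
    chunk_size: int = 100,
    window_count: int = 5,
) -> PairAssignment:
    """Select a collaborator for one user on training data."""
    if user not in block:
        raise ValidationError(f"unknown user {user!r}")
    if len(block) < 2:
        raise ValidationError("matching needs at least 2 members")
    rng = np.random.default_rng(seed) if seed is not None else None
    return _match_one(block, user, strategy, mu, rng, n_folds, chunk_size, window_count)


def match_all(
    block: Mapping[str, EpochedRecording],
    strategy: str = "mimc",
    mu: float = 0.5,
    seed: int | None = None,
    n_folds: int = 5,
    chunk_size: int = 100,
    window_count: int = 5,
) -> list[PairAssignment]:
    """One independent assignment per member (pairings need not be mutual)."""
    if len(block) < 2:
        raise ValidationError("matching needs at least 2 members")
    single_aucs = (
        _single_aucs(block, n_folds, chunk_size, window_count) if strategy in ("ipd", "bip") else None
    )
    ssnr_table = {m: xdawn_ssnr(block[m]).ssnr for m in block} if strategy == "mimc" and len(block) > 2 else None
    out = []
    for i, user in enumerate(block):
        rng = np.random.default_rng([seed, i]) if seed is not None else None
        out.append(
            _match_one(
                block, user, strategy, mu, rng, n_folds, chunk_size, window_count,
                single_aucs=single_aucs, ssnr_table=ssnr_table,
            )
        )
    return out


# ---------------------------------------------------------------------------
# SFFS subgroup selection
# ---------------------------------------------------------------------------

def _mimc_objective(
    block: Mapping[str, EpochedRecording],
    group: list[str],
    candidates: list[str],
    ssnr_table: dict[str, float],
    mu: float,
) -> np.ndarray:
    """MIMC score of each candidate against the group's average-ERP fusion.

    With a single candidate the raw (un-z-scored) combination is returned;
    the argmax/argmin is what matters downstream.
    """
    fused = fuse([block[m] for m in group], "average_erp")
    m_in = np.array([ssnr_table[c] for c in candidates])
    m_co = np.array([collaborative_capability(fused, block[c]) for c in candidates])
    if len(candidates) < 2:
        return mu * m_in + (1.0 - mu) * m_co
    return mu * zscore(m_in) + (1.0 - mu) * zscore(m_co)


def sffs_subgroup(
    block: Mapping[str, EpochedRecording],
    mu: float,
    epsilon: float = 0.0,
    max_size: int | None = None,
    n_folds: int = 5,
    chunk_size: int = 100,
    window_count: int = 5,
) -> Subgroup:
    """Sequential forward floating selection of a collaborative subgroup.

    Starts from the member with the highest individual SSNR, repeatedly adds
    the argmax-MIMC candidate (the current subgroup's fusion playing the role
    of the predefined user), conditionally excludes the argmin-MIMC member
    when that strictly improves the best cross-validated AUC recorded at the
    smaller size, and stops when an accepted inclusion no longer improves CV
    AUC by more than ``epsilon``.
    """
    members = list(block)
    if not members:
        raise ValidationError("empty cohort")
    if max_size is None:
        max_size = len(members)
    max_size = min(max_size, len(members))

    ssnr_table = {m: xdawn_ssnr(block[m]).ssnr for m in members}

    def cv_auc(group: list[str]) -> float:
        return training_cv_auc(
            [block[m] for m in group], "average_erp", n_folds, chunk_size, window_count
        )

    init = members[int(np.argmax([ssnr_table[m] for m in members]))]
    group = [init]
    trace: list[dict] = []
    best_at_size: dict[int, float] = {}
    current_auc = cv_auc(group)
    best_at_size[1] = current_auc
    trace.append({"step": "init", "member": init, "ssnr": ssnr_table[init], "cv_auc": current_auc})

    if len(members) == 1 or max_size == 1:
        return Subgroup(members=group, trace=trace)

    while len(group) < max_size:
        candidates = [m for m in members if m not in group]
        if not candidates:
            break
        j_inc = _mimc_objective(block, group, candidates, ssnr_table, mu)
        s_star = candidates[int(np.argmax(j_inc))]
        new_group = group + [s_star]
        trace.append(
            {
                "step": "inclusion",
                "member": s_star,
                "J": {c: float(v) for c, v in zip(candidates, j_inc)},
            }
        )
        # conditional exclusion: drop the argmin-MIMC member while that beats
        # the best AUC previously recorded at the smaller size
        while len(new_group) > 1:
            j_exc = np.array(
                [
                    _mimc_objective(
                        block, [m for m in new_group if m != s], [s], ssnr_table, mu
                    )[0]
                    for s in new_group
                ]
            )
            s_minus = new_group[int(np.argmin(j_exc))]
            if s_minus == s_star:
                break
            reduced = [m for m in new_group if m != s_minus]
            reduced_auc = cv_auc(reduced)
            prev_best = best_at_size.get(len(reduced), -np.inf)
            if reduced_auc > prev_best:
                trace.append(
                    {
                        "step": "exclusion",
                        "member": s_minus,
                        "J_tilde": {m: float(v) for m, v in zip(new_group, j_exc)},
                        "cv_auc": reduced_auc,
                    }
                )
                new_group = reduced
                best_at_size[len(reduced)] = reduced_auc
            else:
                break
        new_auc = cv_auc(new_group)
        trace.append({"step": "evaluate", "members": list(new_group), "cv_auc": new_auc})
        if new_auc <= current_auc + epsilon:
            trace.append(
                {
                    "step": "terminate",
                    "reason": f"cv_auc {new_auc:.4f} <= {current_auc:.4f} + epsilon",
                    "members": list(group),
                }
            )
            return Subgroup(members=group, trace=trace)
        group = new_group
        current_auc = new_auc
        best = best_at_size.get(len(group), -np.inf)
        best_at_size[len(group)] = max(best, new_auc)
    trace.append({"step": "terminate", "reason": "max size reached", "members": list(group)})
    return Subgroup(members=group, trace=trace)
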