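"""Capability scoring: class templates, xDAWN SSNR, ERP correlation, MIMC, mu search."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cobci.capability import (
    class_templates,
    collaborative_capability,
    mimc_scores,
    mu_grid,
    optimize_mu,
    select_mu,
    xdawn_ssnr,
    zscore,
)
from cobci.core import EpochedRecording, ValidationError
from cobci.crossval import subset_trials
from conftest import random_epochs, small_config


def epochs_from(data, labels):
    data = np.asarray(data, dtype=float)
    return EpochedRecording(
        subject_id="S01", session_id="s", block_id="b", data=data,
        labels=np.asarray(labels, dtype=np.int8), sample_rate=1000.0,
        window_ms=(0.0, data.shape[2]),
        channel_labels=[f"c{i}" for i in range(data.shape[1])],
    )


class TestClassTemplates:
    def test_identical_trials(self):
        t = np.arange(6.0).reshape(2, 3)
        ep = epochs_from([t, t, np.zeros((2, 3))], [1, 1, 0])
        ct = class_templates(ep)
        assert np.array_equal(ct.p1, t)
        assert np.array_equal(ct.p0, np.zeros((2, 3)))
        assert (ct.n0, ct.n1) == (1, 2)

    def test_scalar_arithmetic(self):
        ep = epochs_from([[[1.0]], [[3.0]], [[0.0]]], [1, 1, 0])
        assert class_templates(ep).p1 == pytest.approx(np.array([[2.0]]))

    def test_matches_loop_mean(self):
        ep = random_epochs(7, n_trials=20, n_channels=3, n_samples=6)
        ct = class_templates(ep)
        acc = np.zeros((3, 6))
        n = 0
        for k in range(20):
            if ep.labels[k] == 1:
                acc += ep.data[k]
                n += 1
        assert np.abs(ct.p1 - acc / n).max() < 1e-12

    def test_missing_class(self):
        ep = epochs_from([[[1.0]]], [1])
        with pytest.raises(ValidationError, match="non-target"):
            class_templates(ep)


class TestXdawn:
    def test_single_channel_scalar_ratio(self):
        ep = random_epochs(1, n_trials=30, n_channels=1, n_samples=10)
        res = xdawn_ssnr(ep)
        p1 = ep.data[ep.labels == 1].mean(axis=0)
        num = float((p1 @ p1.T).item())
        den = float(sum((x @ x.T).item() for x in ep.data))
        assert abs(res.filter[0]) == 1.0
        assert res.ssnr == pytest.approx(num / den, rel=1e-6)

    def test_matches_rayleigh_quotient_maximum(self):
        """On 20 random 4-channel instances the generalized eigenvalue equals the
        numerically maximized Rayleigh quotient."""
        for seed in range(20):
            ep = random_epochs(seed, n_trials=25, n_channels=4, n_samples=8)
            res = xdawn_ssnr(ep)
            oracle = _max_rayleigh(res.signal_cov, res.total_cov)
            assert res.ssnr == pytest.approx(oracle, rel=1e-6)

    def test_rotation_invariance(self):
        ep = random_epochs(3, n_trials=30, n_channels=5, n_samples=10)
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((5, 5)))
        rotated = epochs_from(np.einsum("cd,kds->kcs", q, ep.data), ep.labels)
        assert xdawn_ssnr(rotated).ssnr == pytest.approx(xdawn_ssnr(ep).ssnr, rel=1e-8)

    def test_planted_direction_recovery(self):
        """A strong rank-1 subject's leading filter aligns with its topography."""
        from cobci.simdata import SubjectProfile, generate_cohort
        from cobci.preprocess import crop_window

        cfg = small_config(seed=2, n_subjects=1, n_sessions=1, n_blocks=1,
                           n_sequences=10, targets_per_sequence=4)
        topo = np.random.default_rng(5).standard_normal(cfg.n_channels)
        topo -= topo.mean()
        topo /= np.linalg.norm(topo)
        prof = [SubjectProfile("S01", 120.0, 0.8, topo, 7)]
        cohort, _ = generate_cohort(cfg, profiles=prof)
        ep = crop_window(cohort.block("sess1", "block1")["S01"], 0.0, 500.0)
        f = xdawn_ssnr(ep).filter
        assert abs(f @ topo) >= 0.9

    def test_no_targets(self):
        ep = epochs_from([[[1.0]]], [0])
        with pytest.raises(ValidationError, match="target"):
            xdawn_ssnr(ep)


def _max_rayleigh(a, b):
    """Direct numerical maximization of u'Au / u'Bu over unit vectors."""
    from scipy.optimize import minimize

    def neg(u):
        return -(u @ a @ u) / (u @ b @ u)

    best = -np.inf
    for s in range(8):
        u0 = np.random.default_rng(s).standard_normal(a.shape[0])
        r = minimize(neg, u0, method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        best = max(best, -r.fun)
    return best


class TestCollaborativeCapability:
    def test_self_is_one(self):
        ep = random_epochs(0)
        assert collaborative_capability(ep, ep) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        ep = random_epochs(0)
        neg = epochs_from(-ep.data, ep.labels)
        assert collaborative_capability(ep, neg) == pytest.approx(-1.0)

    def test_symmetry_exact(self):
        a = random_epochs(1)
        b = random_epochs(2)
        b = epochs_from(b.data, a.labels)  # pair the label sequences
        assert collaborative_capability(a, b) == collaborative_capability(b, a)

    def test_independent_noise_small_and_matches_double_loop(self):
        a = random_epochs(10, n_trials=280, n_targets=56, n_channels=4, n_samples=30)
        b = random_epochs(11, n_trials=280, n_targets=56, n_channels=4, n_samples=30)
        b = epochs_from(b.data, a.labels)  # pair the label sequences
        sigma = collaborative_capability(a, b)
        assert abs(sigma) <= 0.1
        # explicit per-trial double loop
        acc = 0.0
        n = 0
        for k in range(a.n_trials):
            if a.labels[k] == 1:
                x = a.data[k].ravel()
                y = b.data[k].ravel()
                acc += np.corrcoef(x, y)[0, 1]
                n += 1
        assert sigma == pytest.approx(acc / n, abs=1e-12)

    def test_zero_variance_trial_counts_zero(self):
        a = epochs_from([np.zeros((2, 3)), np.ones((2, 3))], [1, 0])
        b = epochs_from([np.arange(6.0).reshape(2, 3), np.ones((2, 3))], [1, 0])
        with pytest.warns(UserWarning, match="zero-variance"):
            assert collaborative_capability(a, b) == 0.0

    def test_label_mismatch(self):
        a = random_epochs(1)
        b = random_epochs(2)
        flipped = epochs_from(b.data, 1 - b.labels)
        with pytest.raises(ValidationError, match="paired"):
            collaborative_capability(a, flipped)


class TestMimcScores:
    @staticmethod
    def block(seed=0, n_members=4):
        members = {}
        ref = random_epochs(seed, n_trials=40, n_channels=3, n_samples=10)
        for i in range(n_members):
            ep = random_epochs(seed + i, n_trials=40, n_channels=3, n_samples=10,
                               subject_id=f"S{i + 1:02d}")
            members[f"S{i + 1:02d}"] = epochs_from(ep.data, ref.labels)
        return members

    def test_mu_limits_recover_component_rankings(self):
        blk = self.block()
        s1 = mimc_scores("S01", blk, mu=1.0)
        assert np.array_equal(np.argsort(s1.m), np.argsort(s1.m_in))
        s0 = mimc_scores("S01", blk, mu=0.0)
        assert np.array_equal(np.argsort(s0.m), np.argsort(s0.m_co))

    def test_symmetric_cancellation(self):
        m = 0.5 * zscore(np.array([1.0, 2.0, 3.0])) + 0.5 * zscore(np.array([3.0, 2.0, 1.0]))
        assert np.allclose(m, 0.0)

    def test_affine_invariance_of_argmax(self):
        rng = np.random.default_rng(4)
        m_in = rng.standard_normal(6)
        m_co = rng.standard_normal(6)
        base = 0.4 * zscore(m_in) + 0.6 * zscore(m_co)
        shifted = 0.4 * zscore(3.0 * m_in + 7.0) + 0.6 * zscore(0.5 * m_co - 2.0)
        assert np.argmax(base) == np.argmax(shifted)

    def test_zero_spread_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero spread"):
            assert np.allclose(zscore(np.ones(4)), 0.0)

    def test_needs_two_candidates(self):
        blk = self.block(n_members=2)
        with pytest.raises(ValidationError, match="2 candidates"):
            mimc_scores("S01", blk, mu=0.5)

    def test_candidate_order_is_member_order(self):
        blk = self.block()
        s = mimc_scores("S02", blk, mu=0.5)
        assert s.candidate_ids == ["S01", "S03", "S04"]


class TestMuOptimization:
    def test_grid_construction(self):
        assert np.allclose(mu_grid(0.5), [0.0, 0.5, 1.0])
        assert len(mu_grid(0.01)) == 101
        assert mu_grid(0.01)[-1] == 1.0

    def test_constant_table_ties_to_zero(self):
        table = pd.DataFrame({"mu": [0.0, 0.5, 1.0] * 2, "fold": [0] * 3 + [1] * 3,
                              "score": [0.7] * 6})
        assert select_mu(table) == 0.0

    def test_argmax_of_fold_mean(self):
        table = pd.DataFrame({"mu": [0.0, 0.5, 1.0] * 2, "fold": [0] * 3 + [1] * 3,
                              "score": [0.5, 0.9, 0.6, 0.5, 0.8, 0.6]})
        assert select_mu(table) == 0.5

    def test_fold_partition_protocol_sizes(self):
        from cobci.crossval import contiguous_folds

        folds = contiguous_folds(1400, 5, chunk_size=100)
        assert [len(f) for f in folds] == [300, 300, 300, 300, 200]
        assert np.array_equal(np.concatenate(folds), np.arange(1400))

    def test_runs_on_small_cohort(self, analysis_block):
        mu_star, table = optimize_mu(analysis_block, grid_step=0.5, chunk_size=50)
        assert 0.0 <= mu_star <= 1.0
        assert set(table["mu"].unique()) == {0.0, 0.5, 1.0}
        assert table["score"].between(0, 1).all()

    def test_capabilities_use_training_folds_only(self, analysis_block):
        """Corrupting one fold's data changes only that fold's held-out scores'
        dependence, not the grid or structure."""
        mu_star, table = optimize_mu(analysis_block, grid_step=0.5, chunk_size=50)
        n_folds = table["fold"].nunique()
        assert n_folds == 5
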