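"""HDCA classifier and Euclidean-space alignment."""

import numpy as np
import pytest

from cobci.classify import (
    ea_align,
    ea_hdca,
    ea_reference,
    hdca_fit,
    hdca_score,
)
from cobci.core import ValidationError
from cobci.fusion import FusedEpochs, as_fused
from cobci.metrics import auc
from conftest import random_epochs


def fused_from(data, labels):
    data = np.asarray(data, dtype=float)
    return FusedEpochs(
        data=data, labels=np.asarray(labels, dtype=np.int8), member_ids=["S01"],
        strategy="average_erp", sample_rate=250.0,
        window_ms=(0.0, data.shape[2] / 250.0 * 1000.0),
    )


def separable(n=40, n_channels=3, n_samples=25, seed=0, gap=8.0):
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=np.int8)
    labels[: n // 4] = 1
    rng.shuffle(labels)
    data = rng.standard_normal((n, n_channels, n_samples))
    data[labels == 1, 0, :] += gap
    return fused_from(data, labels)


class TestHDCA:
    def test_separable_training_is_perfect(self):
        f = separable()
        model = hdca_fit(f, window_count=5)
        sv = hdca_score(model, f)
        assert auc(sv.scores, f.labels) == 1.0
        assert (sv.scores[f.labels == 1] > model.threshold).all()
        assert (sv.scores[f.labels == 0] <= model.threshold).all()

    def test_sign_convention_targets_high(self):
        for seed in range(5):
            f = separable(seed=seed, gap=2.0)
            model = hdca_fit(f)
            sv = hdca_score(model, f)
            assert sv.scores[f.labels == 1].mean() > sv.scores[f.labels == 0].mean()

    def test_w1_c1_closed_form(self):
        """With one window and one channel the score is affine in the trial mean."""
        rng = np.random.default_rng(2)
        data = rng.standard_normal((30, 1, 10))
        labels = np.zeros(30, dtype=np.int8)
        labels[:8] = 1
        data[labels == 1] += 1.5
        f = fused_from(data, labels)
        model = hdca_fit(f, window_count=1)
        sv = hdca_score(model, f)
        trial_means = data.mean(axis=(1, 2))
        slope = model.spatial_filters[0, 0] * model.temporal_weights[0]
        assert np.abs(sv.scores - slope * trial_means).max() < 1e-10

    def test_score_matches_per_trial_loop(self):
        f = separable(seed=4, gap=1.0)
        model = hdca_fit(f, window_count=5)
        sv = hdca_score(model, f)
        nw = model.window_samples
        for k in range(f.n_trials):
            y = np.array([
                model.spatial_filters[w] @ f.data[k, :, w * nw : (w + 1) * nw].mean(axis=1)
                for w in range(model.window_count)
            ])
            assert sv.scores[k] == pytest.approx(y @ model.temporal_weights, abs=1e-12)

    def test_auc_invariant_to_common_affine_scaling(self):
        f = separable(seed=5, gap=1.0)
        test = separable(seed=6, gap=1.0)
        model = hdca_fit(f)
        base = auc(hdca_score(model, test).scores, test.labels)
        scaled = fused_from(3.7 * test.data + 11.0, test.labels)
        model2 = hdca_fit(fused_from(3.7 * f.data + 11.0, f.labels))
        assert auc(hdca_score(model2, scaled).scores, scaled.labels) == pytest.approx(base)

    def test_indivisible_window(self):
        f = separable(n_samples=23)
        with pytest.raises(ValidationError, match="divisible"):
            hdca_fit(f, window_count=5)

    def test_missing_class(self):
        f = separable()
        f.labels[:] = 0
        with pytest.raises(ValidationError, match="target"):
            hdca_fit(f)

    def test_model_template_ordering(self):
        f = separable(gap=3.0)
        model = hdca_fit(f)
        z0 = model.template_projection_0 @ model.temporal_weights
        z1 = model.template_projection_1 @ model.temporal_weights
        assert z1 > z0


class TestEA:
    def test_single_trial_whitening(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 4, 50))
        f = fused_from(x, [1])
        aligned = ea_align(f, ea_reference(f))
        cov = aligned.data[0] @ aligned.data[0].T
        assert np.abs(cov - np.eye(4)).max() < 1e-8

    def test_identity_fixed_point(self):
        rng = np.random.default_rng(1)
        # trials built to have mean covariance exactly identity
        n, c, s = 60, 3, 40
        data = rng.standard_normal((n, c, s))
        f = fused_from(data, np.r_[np.ones(10), np.zeros(50)])
        ref = ea_reference(f)
        aligned = ea_align(f, ref)
        ref2 = ea_reference(aligned)
        assert np.abs(ref2.mean_cov - np.eye(c)).max() < 1e-8
        assert np.abs(ref2.inv_sqrt - np.eye(c)).max() < 1e-6

    def test_inverse_square_root_property(self):
        rng = np.random.default_rng(2)
        f = fused_from(rng.standard_normal((20, 3, 30)), np.r_[np.ones(5), np.zeros(15)])
        ref = ea_reference(f)
        assert np.abs(ref.inv_sqrt @ ref.mean_cov @ ref.inv_sqrt - np.eye(3)).max() < 1e-8

    def test_align_with_identity_reference_is_noop(self):
        from cobci.classify import EAReference

        f = separable()
        ref = EAReference(mean_cov=np.eye(3), inv_sqrt=np.eye(3), n_trials=1)
        aligned = ea_align(f, ref)
        assert np.allclose(aligned.data, f.data)

    def test_mean_covariance_identity_after_alignment(self):
        """Alignment property on simulated (full-rank) data: whitened mean trial
        covariance equals the identity."""
        from cobci.preprocess import PreprocessParams
        from cobci.simdata import generate_cohort
        from conftest import small_config

        cfg = small_config(seed=6, n_subjects=1, n_sessions=1, n_blocks=1,
                           preprocess=PreprocessParams(car=False))
        cohort, _ = generate_cohort(cfg)
        f = as_fused(cohort.block("sess1", "block1")["S01"])
        aligned = ea_align(f, ea_reference(f))
        n = aligned.n_trials
        cov = np.einsum("kcs,kds->cd", aligned.data, aligned.data) / n
        assert np.linalg.norm(cov - np.eye(aligned.n_channels)) < 1e-8

    def test_alignment_identity_on_support_for_car_data(self, small_cohort):
        """Common-average-referenced data has one zero-variance direction; the
        aligned mean covariance equals the identity on the data's support."""
        cohort, _ = small_cohort
        f = as_fused(cohort.block("sess1", "block1")["S01"])
        ref = ea_reference(f)
        aligned = ea_align(f, ref)
        cov = np.einsum("kcs,kds->cd", aligned.data, aligned.data) / aligned.n_trials
        c = aligned.n_channels
        support = np.eye(c) - np.ones((c, c)) / c  # CAR removes the channel mean
        assert np.linalg.norm(cov - support) < 1e-8

    def test_zero_data_rejected(self):
        f = fused_from(np.zeros((3, 2, 10)), [1, 0, 0])
        with pytest.raises(ValidationError, match="degenerate"):
            ea_reference(f)

    def test_ea_hdca_same_domain_equals_align_then_fit(self):
        f = separable(gap=1.5)
        sv1 = ea_hdca(f, f)
        aligned = ea_align(f, ea_reference(f))
        model = hdca_fit(aligned)
        sv2 = hdca_score(model, aligned)
        assert np.allclose(sv1.scores, sv2.scores)
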