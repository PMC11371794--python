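# Methods

This note documents the models and procedures implemented in `cobci`, the
assumptions behind the synthetic cohort generator, and the numerical choices
that matter when reproducing or extending the results.

## Capability scores and two-user matching

For a candidate collaborator with preprocessed epochs `X_k ∈ R^{C×S}`
(trials `k = 1…N_T`, labels 0/1), the class templates are the arithmetic
means of the non-target and target trials, `P⁽⁰⁾` and `P⁽¹⁾`.

**Individual capability (xDAWN SSNR).** The score is the largest
generalized eigenvalue `ρ` of the pair

    Σ̂⁽¹⁾ = P⁽¹⁾ P⁽¹⁾ᵀ        (target-template covariance, C×C)
    Σ̂    = Σ_k X_k X_kᵀ       (total data covariance, C×C)

which equals the maximum over spatial filters `u` of the Rayleigh quotient
`uᵀΣ̂⁽¹⁾u / uᵀΣ̂u` — the signal to signal-plus-noise ratio after spatial
filtering. Both covariances are formed in channel space so the quadratic
forms are well defined. Only the leading eigenvalue is used as a score; the
leading eigenvector is reported for diagnostics.

Numerics: a ridge `1e-9·trace(Σ̂)/C` is added to `Σ̂`, and the eigenproblem
is solved on the support of `Σ̂` (eigendirections with eigenvalue
`> 1e-9·λ_max`). The support restriction matters: common-average
referencing (CAR) makes the channel-mean direction exactly zero-variance,
and without the restriction that null direction rides into the leading
eigenvector through the near-zero denominator, destroying the filter (the
reported eigenvalue is barely affected, but planted-direction recovery
drops from ≥ 0.97 alignment to ~0.5).

**Collaborative capability.** For a user/candidate pair with identical
stimulus schedules, the score `σ` is the mean over target trials of the
Pearson correlation between the two subjects' flattened (channels ×
samples) trials. It is symmetric, lies in [−1, 1], and a zero-variance
trial contributes 0 (with a warning).

**MIMC.** Candidates are ranked by `M = μ·z(M_in) + (1−μ)·z(M_co)`, where
`z` is the population z-score (divide by N) across the candidate set —
the population form keeps the 3-candidate symmetry case exact. Ties in any
argmax resolve to the lowest member index, making every selection
deterministic.

**Choosing μ.** Five-fold cross-validation on the training block: trials
are split into five contiguous folds (300/300/300/300/200 for the full
1400-trial block; fold boundaries fall on 100-trial sequence chunks so the
4-targets-per-100 class structure is preserved; scaled-down blocks pass an
explicit `chunk_size`). For each fold and each μ on a grid (step 0.01 by
default), capabilities are computed from the four training folds only, each
member is paired with its argmax-M candidate, the pair is fused by ERP
averaging, and an HDCA model trained on the training folds is scored on the
held-out fold. The μ with the highest fold-mean AUC wins; ties go to the
smallest μ. Pairings and pair AUCs are cached per fold, so the 101-point
grid costs little more than the distinct pairings it induces.

## Subgroup selection (SFFS with MIMC)

Initialization: the member with the highest individual SSNR. Each
iteration then (i) treats the current subgroup's average-ERP fusion as the
predefined user and includes the candidate maximizing the MIMC score;
(ii) conditionally excludes the member whose MIMC score against the fusion
of the others is minimal, but only when that member is not the one just
added and removing it strictly improves on the best cross-validated AUC
recorded at the smaller size (repeating while that holds); (iii) stops when
an accepted step no longer improves CV AUC by more than `epsilon`
(default 0, strict improvement) or the size cap is reached. Every
inclusion, exclusion and AUC evaluation is recorded in the returned trace.
The exclusion rule (argmin of the member-vs-rest score, guarded by the AUC
record) is one concrete operationalization of floating selection; it keeps
the procedure deterministic and auditable.

Baseline matching strategies (`random`, `ipd`, `bip`, `bcp`) use the same
contiguous-fold CV convention; IPD is implemented as a pure argmin of
single-subject AUC dissimilarity without a manual threshold.

## Fusion

Centralized: average ERP (element-wise mean), parallel combination
(channel-axis concatenation) and serial combination (time-axis
concatenation), all requiring identical label sequences. Distributed:
weighted voting combines *threshold-centered continuous scores*,
`Σ w_i (Z_{k,i} − Zth_i) / Σ w_i`, rather than hard labels, so ROC analysis
remains possible; with weights concentrated on one member it reduces
exactly to that member's decisions. Signal-space averaging is the only AE
variant implemented (feature-space averaging is a documented alternative).

## HDCA and Euclidean alignment

HDCA splits the analysis window into `W` non-overlapping windows (default
5; with the default 0–500 ms window at 250 Hz, 125 samples → 25 per
window). Per window, every sample is an observation for a spatial Fisher
discriminant `u_w ∝ S_W⁻¹(mean₀ − mean₁)`; each trial's window feature is
the mean of the spatially projected samples in the window (the standard
reduction of the window to one value per trial). A temporal Fisher
discriminant `v` then combines the `W` features, and the decision threshold
is the midpoint of the projected class templates. Both stages are
sign-normalized so target trials score high — this makes the "score above
threshold → label 1" rule correct regardless of which class the raw
discriminant direction points at. Scatter matrices carry a ridge
`1e-6·trace/dim`.

EA computes a per-domain reference `R = (1/n) Σ X_k X_kᵀ` over all trials
(labels unused, so it is test-time legal) and whitens every trial by
`R^{−1/2}`, computed by symmetric eigendecomposition with a rank cutoff at
`1e-10·λ_max`: zero-variance directions (the CAR channel-mean direction)
are left untouched rather than amplified. After alignment the mean trial
covariance equals the identity on the data's support — exactly the
identity for full-rank data, identity-minus-channel-mean-projector for
CAR-referenced data. EA-HDCA aligns the training domain with its own
reference, the evaluated test set with its own reference, then trains and
scores HDCA on the aligned data.

## Evaluation protocols

All selection and training — μ, capabilities, matching, SFFS, HDCA and its
threshold — use block 1 of the training session only; blocks 2 and 3 of
the test session are the test set. Within-session runs use plain HDCA,
cross-session runs EA-HDCA. AUC is the tie-corrected Mann–Whitney
statistic on the continuous scores; TPR/FPR come from the threshold rule.
The `matched` group mode enumerates all candidates and reports each user's
best *test* AUC — a non-deployable oracle ceiling, flagged as such in the
report. Random-grouping curves cap the subsets drawn per group size at 100.
Reports carry a configuration hash, the seed, and archived per-trial
scores so every aggregate can be recomputed.

## The synthetic cohort generator

The simulator emulates the pseudo-collaborative cross-session RSVP
protocol; its defaults are the protocol constants (14 subjects, 62
channels, 1000 Hz, 2 sessions × 3 blocks, 14 × 100 images at 10 Hz, 4
targets/sequence, ≥ 500 ms target gap, 2 s between sequences). Target
positions are drawn by rejection sampling, which is exactly uniform over
the placements satisfying the gap constraint.

Planted structure per subject: an ERP amplitude `a_s` (uniform 40–120 µV ×
unit-norm waveform by default, calibrated so the full-scale single-subject
within-session AUC lands near 0.85), a shared-weight `w_s ∈ [0,1]`, a
rank-1 scalp topography, and an idiosyncratic waveform seed. Target epochs
carry `a_s · u_s(t)` with `u_s` the *unit-norm* mixture
`w_s·p + (1−w_s)·q_s`: normalizing the mixture makes `a_s` alone control
the SSNR while `w_s` only shapes the pairwise correlation (≈ monotone in
`w_s·w_s'`).

Design choices that matter, all made so that planted parameters map onto
method behavior uniformly:

* The shared template `p` is a P300-like biphasic waveform (negative
  deflection at 150 ms, positive ~80 ms-wide peak at 350 ms) and the
  idiosyncratic `q_s` is a random-sign sum of Gaussian bumps at the five
  analysis-window centers, orthogonalized to `p`. Component latencies sit
  at window centers because HDCA's window-mean features otherwise penalize
  waveforms whose peaks straddle window boundaries, giving subjects random
  "window-friendliness" that swamps planted amplitude.
* Both waveform families are band-limited to 2–30 Hz at construction so the
  preprocessing band-pass is energy-neutral for every subject.
* Topographies are zero-mean (CAR leaves them unscaled) and mix a
  cohort-shared map with a subject-specific map (similarity 0.75),
  reflecting the spatial similarity of P300 topographies across people —
  and required for flattened-trial correlations to track `w_s·w_s'` rather
  than random topography overlaps.
* Noise is spatially mixed 1/f ("pink", 70%) plus white (30%), 10 µV per
  channel; the pink-noise spatial mixing is cohort-level with mild
  anisotropy (singular values 0.8–1.2), so noise power along any
  topography is comparable across subjects. Optionally, members of
  configured groups share a pink-noise source (`noise_coupling`), emulating
  common artifacts picked up by subjects recorded simultaneously — the one
  mechanism by which measured ERP correlation can be genuinely misleading
  about fusion benefit.
* The session-2 transform is a symmetric positive-definite channel mixing
  (`I + s·AAᵀ/C`, condition ≈ 4 at the default strength 1.0) plus a 1.2×
  noise-scale change. SPD mixing is the covariance-shift class that
  whitening-based alignment removes exactly (a general linear mixing leaves
  an orthogonal residual that EA cannot correct, and empirically erases
  most of EA's advantage).

Everything derives deterministically from the master seed (schedules,
profiles, noise, transforms), so identical configurations are bit-identical.

What the simulator does **not** model: eye/muscle artifacts, behavioral
responses, non-stationarity within a session, latency jitter of the ERP,
volume-conduction forward models, or multi-source spatial patterns. Passing
tests therefore demonstrate that the selection/fusion/classification
machinery recovers planted structure under a plausible noise model — not
performance on real EEG.

## Preprocessing

Decimation to 250 Hz (zero-phase 8th-order Butterworth anti-alias low-pass
at 0.8× target Nyquist, integer decimation, onsets rescaled), segmentation
into [−200, 1000) ms epochs, zero-phase 4th-order Butterworth band-pass
2–30 Hz applied per epoch (reflect-padded by six cycles of the low edge —
the 2 Hz edge rings for seconds, and shorter padding visibly breaks the
zero-phase symmetry of filtered pulses), common-average re-reference, and
a [0, 500) ms analysis crop at analysis time. Windows are half-open with
0-based sample indexing throughout; sample counts are
`round((end−start)/1000·rate)`. Baseline correction exists but is off by
default; an option to filter the continuous record before segmentation is
provided since filtering epochs is the stated order but unusual.

## Problem sizes used in the tests

The test and acceptance suites run the full pipeline on reduced cohorts
(typically 5–10 subjects, 8 channels, 250 Hz native rate, 6–14 sequences of
50 images), which preserve the protocol's structure — sequences, target
density, gap constraint, contiguous CV folds — at a fraction of the cost;
protocol-conformance checks generate one subject-block at the full 62
channel / 1000 Hz / 1400-trial scale. The μ grid uses step 0.1 in the
regime-recovery tests and 0.01 by default in the API.

## Known limitations

* The SSNR saturates (`ρ → const`) when single-trial signal energy
  dominates the total covariance; at extreme planted amplitudes the filter
  direction (not the score) becomes ill-determined.
* ERP responses overlapping adjacent epochs at 10 Hz presentation are a
  property of the paradigm and are reproduced, not corrected (no
  overlap-aware template estimation).
* `optimize_mu` assumes every fold contains both classes; folds that do not
  are skipped with a warning.
* Weighted voting assumes score scales are comparable after threshold
  centering; no per-member score normalization is applied.
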