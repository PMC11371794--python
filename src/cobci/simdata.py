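"""Synthetic multi-subject, multi-session RSVP EEG with planted ground truth.

The simulator emulates a pseudo-collaborative RSVP target-detection protocol:
a cohort of subjects views the same 10 Hz image stream (14 sequences of 100
images per block, 4 targets per sequence with at least 500 ms between
consecutive targets), over 2 sessions of 3 blocks each, recorded at 1000 Hz
from 62 channels.  Those protocol constants are the defaults of
:class:`SimConfig`; every count can be scaled down for fast experiments.

Planted structure
-----------------
Each subject has

* an ERP amplitude ``a_s`` (individual signal strength -> individual SSNR),
* a shared-weight ``w_s`` in [0, 1] mixing a cohort-shared P300-like template
  ``p(t)`` with a subject-specific smooth waveform ``q_s(t)``
  (pairwise target-ERP correlation grows with ``w_s * w_s'``),
* a unit-norm rank-1 scalp topography.

Target epochs carry ``s(t) = a_s * u(t)`` with ``u`` the unit-norm mixture
``w_s * p(t) + (1 - w_s) * q_s(t)``, spatialized by the topography;
non-target epochs carry noise only.  Noise is
spatially mixed 1/f ("pink") plus white noise.  Session 2 data pass through a
near-identity channel-mixing matrix with a noise-scale change — exactly the
covariance shift that Euclidean-space alignment removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .core import CohortIndex, EpochedRecording, Event, RawRecording, ValidationError
from .preprocess import PreprocessParams, preprocess_block

__all__ = [
    "StimulusSchedule",
    "SubjectProfile",
    "SessionTransform",
    "SimConfig",
    "InfeasibleScheduleError",
    "generate_schedule",
    "make_profiles",
    "generate_raw_block",
    "generate_cohort",
    "shared_template",
    "idiosyncratic_waveform",
]


class InfeasibleScheduleError(ValueError):
    """The requested target count/gap combination admits no valid placement."""


@dataclass(frozen=True)
class StimulusSchedule:
    """A block's stimulus stream: onset times (ms), labels and sequence indices."""

    onsets_ms: np.ndarray
    labels: np.ndarray
    sequence_index: np.ndarray
    rate_hz: float
    n_sequences: int
    images_per_sequence: int
    targets_per_sequence: int
    min_target_gap_ms: float
    inter_sequence_gap_ms: float

    def __post_init__(self) -> None:
        slot = round(1000.0 / self.rate_hz)
        for s in range(self.n_sequences):
            on = self.onsets_ms[self.sequence_index == s]
            if on.size and not np.allclose(np.diff(on), slot):
                raise ValidationError(f"sequence {s}: onsets not spaced by {slot} ms")
            lab = self.labels[self.sequence_index == s]
            if lab.sum() != self.targets_per_sequence:
                raise ValidationError(
                    f"sequence {s}: {lab.sum()} targets, expected {self.targets_per_sequence}"
                )
        gaps = np.diff(self.onsets_ms[self.labels == 1])
        if gaps.size and gaps.min() < self.min_target_gap_ms:
            raise ValidationError(
                f"consecutive target gap {gaps.min():g} ms < minimum {self.min_target_gap_ms:g} ms"
            )

    @property
    def n_events(self) -> int:
        return len(self.onsets_ms)

    def events(self, sample_rate: float) -> list[Event]:
        """Schedule as 0-based sample-indexed events at the given rate."""
        return [
            Event(int(round(o / 1000.0 * sample_rate)), int(l), int(s))
            for o, l, s in zip(self.onsets_ms, self.labels, self.sequence_index)
        ]

    def duration_ms(self) -> float:
        slot = round(1000.0 / self.rate_hz)
        return float(self.onsets_ms[-1] + slot + self.inter_sequence_gap_ms)


def generate_schedule(
    n_sequences: int = 14,
    images_per_sequence: int = 100,
    targets_per_sequence: int = 4,
    rate_hz: float = 10.0,
    min_target_gap_ms: float = 500.0,
    seed: int = 0,
    inter_sequence_gap_ms: float = 2000.0,
) -> StimulusSchedule:
    """Generate one block's stimulus schedule.

    Target positions are drawn uniformly at random among all placements that
    respect the within-sequence gap constraint (rejection sampling from the
    uniform distribution over position subsets is exactly uniform over the
    feasible sets).  Sequences are separated by ``inter_sequence_gap_ms``
    (subjects re-start each sequence), so cross-sequence target gaps always
    exceed the minimum.
    """
    slot = round(1000.0 / rate_hz)
    gap_slots = int(np.ceil(min_target_gap_ms / slot))
    if targets_per_sequence * gap_slots > images_per_sequence:
        raise InfeasibleScheduleError(
            f"{targets_per_sequence} targets with a {min_target_gap_ms} ms gap do not fit "
            f"in {images_per_sequence} images at {rate_hz} Hz"
        )
    if inter_sequence_gap_ms < min_target_gap_ms:
        raise InfeasibleScheduleError(
            "inter_sequence_gap_ms must be >= min_target_gap_ms to honor the gap across sequences"
        )
    rng = np.random.default_rng(seed)
    onsets, labels, seq_idx = [], [], []
    t0 = 0.0
    for s in range(n_sequences):
        if targets_per_sequence > 0:
            for _ in range(100_000):
                pos = np.sort(rng.choice(images_per_sequence, size=targets_per_sequence, replace=False))
                if targets_per_sequence == 1 or np.diff(pos).min() >= gap_slots:
                    break
            else:  # pragma: no cover - astronomically unlikely for feasible inputs
                raise InfeasibleScheduleError("rejection sampling failed to find a valid placement")
            target_pos = set(pos.tolist())
        else:
            target_pos = set()
        for i in range(images_per_sequence):
            onsets.append(t0 + i * slot)
            labels.append(1 if i in target_pos else 0)
            seq_idx.append(s)
        t0 += images_per_sequence * slot + inter_sequence_gap_ms
    return StimulusSchedule(
        onsets_ms=np.asarray(onsets, dtype=float),
        labels=np.asarray(labels, dtype=np.int8),
        sequence_index=np.asarray(seq_idx, dtype=np.int64),
        rate_hz=rate_hz,
        n_sequences=n_sequences,
        images_per_sequence=images_per_sequence,
        targets_per_sequence=targets_per_sequence,
        min_target_gap_ms=min_target_gap_ms,
        inter_sequence_gap_ms=inter_sequence_gap_ms,
    )


@dataclass(frozen=True)
class SubjectProfile:
    """Planted ground truth for one simulated subject."""

    member_id: str
    erp_amplitude: float
    shared_weight: float
    topography: np.ndarray
    idio_seed: int

    def __post_init__(self) -> None:
        if self.erp_amplitude < 0:
            raise ValidationError("erp_amplitude must be >= 0")
        if not 0.0 <= self.shared_weight <= 1.0:
            raise ValidationError("shared_weight must be in [0, 1]")
        topo = np.asarray(self.topography, dtype=float)
        if not np.isclose(np.linalg.norm(topo), 1.0, atol=1e-8):
            raise ValidationError("topography must have unit Euclidean norm")
        object.__setattr__(self, "topography", topo)


@dataclass(frozen=True)
class SessionTransform:
    """Fixed linear channel mixing + noise-scale change applied to session-2 data."""

    gain: np.ndarray
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValidationError("gain must be a square matrix")
        if np.linalg.cond(g) > 100.0:
            raise ValidationError("gain condition number exceeds 100 (must stay invertible)")
        if self.noise_scale <= 0:
            raise ValidationError("noise_scale must be > 0")
        object.__setattr__(self, "gain", g)


@dataclass(frozen=True)
class SimConfig:
    """Full simulator configuration.  Defaults emulate the reference protocol:
    14 subjects, 62 channels, 1000 Hz, 2 sessions x 3 blocks, 14 sequences x
    100 images per block at 10 Hz with 4 targets per sequence and a 500 ms
    minimum gap between consecutive targets."""

    n_subjects: int = 14
    n_channels: int = 62
    sample_rate: float = 1000.0
    n_sessions: int = 2
    n_blocks: int = 3
    n_sequences: int = 14
    images_per_sequence: int = 100
    targets_per_sequence: int = 4
    rate_hz: float = 10.0
    min_target_gap_ms: float = 500.0
    inter_sequence_gap_ms: float = 2000.0
    # subject population (chosen once as plausible single-trial ERP statistics)
    amplitude_range: tuple[float, float] = (40.0, 120.0)  # uV per unit-norm waveform
    shared_weight_range: tuple[float, float] = (0.3, 0.9)
    # P300 topographies are broadly similar across people (central-parietal);
    # each subject's rank-1 topography mixes a cohort-shared map with a
    # subject-specific random map in this proportion
    topography_similarity: float = 0.75
    # noise model
    noise_std: float = 10.0  # per-channel uV
    pink_fraction: float = 0.7
    pink_floor_hz: float = 1.0
    # optional shared-noise coupling: members of a group share a pink-noise
    # source with this mixing coefficient, emulating common artifacts or
    # interference picked up by subjects recorded simultaneously.
    # () = fully independent noise (default).
    noise_coupling: float = 0.0
    noise_coupling_groups: tuple[tuple[int, ...], ...] = ()
    # session-2 covariance shift
    session_gain_strength: float = 1.0
    session_noise_scale: float = 1.2
    seed: int = 0
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_channels", "n_sessions", "n_blocks", "n_sequences", "images_per_sequence"):
            if getattr(self, name) < 1:
                raise ValidationError(f"SimConfig.{name} must be >= 1")


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

_ERP_DURATION_MS = 700.0
_ERP_BAND_HZ = (2.0, 30.0)  # planted components live in the standard ERP analysis band


def _time_ms(sample_rate: float) -> np.ndarray:
    n = int(round(_ERP_DURATION_MS / 1000.0 * sample_rate))
    return np.arange(n) / sample_rate * 1000.0


def _bandlimit(x: np.ndarray, sample_rate: float) -> np.ndarray:
    """Restrict a waveform to the ERP band so the preprocessing band-pass is
    energy-neutral for every subject (planted SNR survives the pipeline)."""
    sos = scipy.signal.butter(4, _ERP_BAND_HZ, btype="band", fs=sample_rate, output="sos")
    return scipy.signal.sosfiltfilt(sos, x, padtype="even")


def shared_template(sample_rate: float) -> np.ndarray:
    """Cohort-shared P300-like template: a positive peak at 350 ms (~80 ms
    wide) preceded by a smaller negative deflection at 150 ms, band-limited to
    the ERP analysis band; unit Euclidean norm.

    Component latencies sit at the centers of the standard 100 ms analysis
    windows so that planted amplitude maps onto windowed-classifier evidence
    the same way for every waveform in the simulator.
    """
    t = _time_ms(sample_rate)
    sigma_p = 80.0 / 2.355  # FWHM -> sigma
    p = np.exp(-0.5 * ((t - 350.0) / sigma_p) ** 2) - 0.45 * np.exp(-0.5 * ((t - 150.0) / 21.0) ** 2)
    p = _bandlimit(p, sample_rate)
    return p / np.linalg.norm(p)


def idiosyncratic_waveform(idio_seed: int, sample_rate: float) -> np.ndarray:
    """Smooth unit-norm subject-specific waveform, orthogonalized to the shared template."""
    rng = np.random.default_rng(idio_seed)
    t = _time_ms(sample_rate)
    # random-sign Gaussian bumps at the same latencies and widths as the
    # shared template's components, so the whole pipeline (band-pass,
    # windowed classifiers) treats shared and idiosyncratic waveforms alike
    # and only amplitude / correlation structure differs across subjects
    q = np.zeros_like(t)
    width = 70.0 / 2.355  # FWHM -> sigma
    for center in (50.0, 150.0, 250.0, 350.0, 450.0):
        q += rng.standard_normal() * np.exp(-0.5 * ((t - center) / width) ** 2)
    q = _bandlimit(q, sample_rate)
    p = shared_template(sample_rate)
    q -= (q @ p) * p
    nrm = np.linalg.norm(q)
    if nrm == 0:  # pragma: no cover - measure-zero
        raise ValidationError("degenerate idiosyncratic waveform")
    return q / nrm


def subject_erp(profile: SubjectProfile, sample_rate: float) -> np.ndarray:
    """Planted single-trial target ERP time course for one subject.

    The shared/idiosyncratic mixture is re-normalized to unit energy so that
    ``erp_amplitude`` alone controls the ERP norm (hence the individual SSNR)
    while ``shared_weight`` only shapes the waveform (hence the pairwise
    correlation).
    """
    p = shared_template(sample_rate)
    q = idiosyncratic_waveform(profile.idio_seed, sample_rate)
    mix = profile.shared_weight * p + (1.0 - profile.shared_weight) * q
    nrm = np.linalg.norm(mix)
    if nrm == 0:
        return 0.0 * mix
    return profile.erp_amplitude * mix / nrm


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _seed_for(config_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, *key]))


_SCHED, _PROFILE, _NOISE, _SESSION = 1, 2, 3, 4


def make_profiles(config: SimConfig) -> list[SubjectProfile]:
    """Draw the cohort's planted subject profiles from the configured population."""
    rng = _seed_for(config.seed, _PROFILE)

    def _zero_mean_unit(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()  # CAR-invariant maps: common-average reference leaves them unscaled
        return v / np.linalg.norm(v)

    shared_topo = _zero_mean_unit(rng.standard_normal(config.n_channels))
    sim = config.topography_similarity
    profiles = []
    for i in range(config.n_subjects):
        amp = rng.uniform(*config.amplitude_range)
        w = rng.uniform(*config.shared_weight_range)
        own = _zero_mean_unit(rng.standard_normal(config.n_channels))
        topo = _zero_mean_unit(sim * shared_topo + (1.0 - sim) * own)
        idio = int(rng.integers(0, 2**31 - 1))
        profiles.append(
            SubjectProfile(
                member_id=f"S{i + 1:02d}",
                erp_amplitude=float(amp),
                shared_weight=float(w),
                topography=topo,
                idio_seed=idio,
            )
        )
    return profiles


def make_session_transform(config: SimConfig, session: int) -> SessionTransform:
    """Channel mixing applied to sessions after the first; identity for session 0.

    Built symmetric positive definite (``I + s A A^T / N_C``): day-to-day
    electrode gain/impedance and conductivity changes couple channels without
    rotating the signal space, which is the covariance-shift class that
    Euclidean-space alignment removes.
    """
    if session == 0:
        return SessionTransform(gain=np.eye(config.n_channels), noise_scale=1.0)
    rng = _seed_for(config.seed, _SESSION, session)
    a = rng.standard_normal((config.n_channels, config.n_channels))
    gain = np.eye(config.n_channels) + config.session_gain_strength * (a @ a.T) / config.n_channels
    # keep the mixing comfortably invertible
    while np.linalg.cond(gain) > 50.0:  # pragma: no cover - strengths used keep cond small
        gain = 0.5 * (gain + np.eye(config.n_channels))
    return SessionTransform(gain=gain, noise_scale=config.session_noise_scale)


def block_schedule(config: SimConfig, session: int, block: int) -> StimulusSchedule:
    """The stimulus schedule shared by all subjects in one (session, block)."""
    seed = int(_seed_for(config.seed, _SCHED, session, block).integers(0, 2**31 - 1))
    return generate_schedule(
        n_sequences=config.n_sequences,
        images_per_sequence=config.images_per_sequence,
        targets_per_sequence=config.targets_per_sequence,
        rate_hz=config.rate_hz,
        min_target_gap_ms=config.min_target_gap_ms,
        seed=seed,
        inter_sequence_gap_ms=config.inter_sequence_gap_ms,
    )


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, sample_rate: float, floor_hz: float) -> np.ndarray:
    """Unit-variance 1/f noise per channel (spectrum ~ 1/sqrt(f) amplitude)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    scale = 1.0 / np.sqrt(np.maximum(freqs, floor_hz))
    spec *= scale
    out = np.fft.irfft(spec, n=n_samples, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def _noise_mixing(config: SimConfig) -> np.ndarray:
    """Cohort-level spatial mixing for the pink-noise sources.

    Volume conduction correlates channels for everyone alike, so the mixing is
    shared across subjects and sessions.  Built as ``Q1 diag(d) Q2^T`` with
    mild singular-value spread so every spatial direction carries comparable
    noise power while channels stay clearly correlated.
    """
    rng = _seed_for(config.seed, _NOISE)
    c = config.n_channels
    q1, _ = np.linalg.qr(rng.standard_normal((c, c)))
    q2, _ = np.linalg.qr(rng.standard_normal((c, c)))
    d = rng.uniform(0.8, 1.2, size=c)
    return q1 @ np.diag(d) @ q2.T


def generate_raw_block(
    config: SimConfig,
    profile: SubjectProfile,
    schedule: StimulusSchedule,
    subject_index: int,
    session: int,
    block: int,
) -> RawRecording:
    """Continuous data for one (subject, session, block): noise + planted target ERPs."""
    if len(profile.topography) != config.n_channels:
        raise ValidationError(
            f"topography length {len(profile.topography)} != n_channels {config.n_channels}"
        )
    sr = config.sample_rate
    pad = int(round(sr))  # 1 s lead-in so pre-trigger epoch windows fit
    n_samples = (
        pad
        + int(round(schedule.duration_ms() / 1000.0 * sr))
        + int(round(_ERP_DURATION_MS / 1000.0 * sr))
    )
    rng = _seed_for(config.seed, _NOISE, subject_index, session, block)

    transform = make_session_transform(config, session)
    noise = np.zeros((config.n_channels, n_samples))
    if config.noise_std > 0:
        pink = _pink_noise(rng, config.n_channels, n_samples, sr, config.pink_floor_hz)
        c = config.noise_coupling
        group = next(
            (g for g, idxs in enumerate(config.noise_coupling_groups) if subject_index in idxs),
            None,
        )
        if c > 0.0 and group is not None:
            common_rng = _seed_for(config.seed, _NOISE, 1_000_000 + group, session, block)
            common = _pink_noise(common_rng, config.n_channels, n_samples, sr, config.pink_floor_hz)
            pink = np.sqrt(1.0 - c * c) * pink + c * common
        mix = _noise_mixing(config)
        white = rng.standard_normal((config.n_channels, n_samples))
        noise = config.noise_std * (
            config.pink_fraction * (mix @ pink) + (1.0 - config.pink_fraction) * white
        )
        noise *= transform.noise_scale

    erp = subject_erp(profile, sr)
    data = noise
    events = [Event(e.onset_sample + pad, e.label, e.sequence_index) for e in schedule.events(sr)]
    for e in events:
        if e.label == 1:
            data[:, e.onset_sample : e.onset_sample + erp.size] += np.outer(profile.topography, erp)
    data = transform.gain @ data
    return RawRecording(
        subject_id=profile.member_id,
        session_id=f"sess{session + 1}",
        block_id=f"block{block + 1}",
        sample_rate=sr,
        channel_labels=[f"ch{c + 1}" for c in range(config.n_channels)],
        data=data.astype(np.float32),
        events=events,
    )


def generate_cohort(
    config: SimConfig,
    profiles: list[SubjectProfile] | None = None,
    preprocess: bool = True,
) -> tuple[CohortIndex, list[SubjectProfile]]:
    """Generate the full cohort and return it with its ground-truth profiles.

    Each (subject, session, block) is synthesized as a continuous recording and
    run through the standard preprocessing chain (or segmented raw if
    ``preprocess=False``).  Identical configs (including seed) yield
    bit-identical cohorts.
    """
    if profiles is None:
        profiles = make_profiles(config)
    if len(profiles) != config.n_subjects:
        raise ValidationError(f"{len(profiles)} profiles for {config.n_subjects} subjects")
    params = config.preprocess
    if not preprocess:
        params = replace(params, target_rate=config.sample_rate, car=False)
    recordings: dict[tuple[str, str, str], EpochedRecording] = {}
    for session in range(config.n_sessions):
        for block in range(config.n_blocks):
            schedule = block_schedule(config, session, block)
            for i, prof in enumerate(profiles):
                raw = generate_raw_block(config, prof, schedule, i, session, block)
                if preprocess:
                    epochs = preprocess_block(raw, params)
                else:
                    from .preprocess import segment

                    epochs = segment(raw, params.epoch_tmin_ms, params.epoch_tmax_ms)
                recordings[(prof.member_id, raw.session_id, raw.block_id)] = epochs
    cohort = CohortIndex(members=[p.member_id for p in profiles], recordings=recordings)
    return cohort, profiles
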