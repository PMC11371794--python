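"""Standard RSVP ERP preprocessing: decimate, segment, band-pass, re-reference, crop.

The default parameter set is the usual single-trial ERP pipeline for 10 Hz
RSVP streams: decimation to 250 Hz, epochs spanning [-200, 1000) ms around
each trigger, a zero-phase 2-30 Hz 4th-order Butterworth band-pass applied
per epoch, common-average re-referencing, and a [0, 500) ms analysis crop.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .core import EpochedRecording, Event, RawRecording, ValidationError, n_window_samples

__all__ = [
    "PreprocessParams",
    "downsample",
    "segment",
    "bandpass",
    "rereference_car",
    "crop_window",
    "preprocess_block",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters for :func:`preprocess_block` (defaults: the standard pipeline)."""

    target_rate: float = 250.0
    epoch_tmin_ms: float = -200.0
    epoch_tmax_ms: float = 1000.0
    band_low_hz: float = 2.0
    band_high_hz: float = 30.0
    car: bool = True
    baseline_correct: bool = False  # off: not part of the standard chain here
    filter_continuous: bool = False  # band-pass before segmentation instead of after


def downsample(raw: RawRecording, target_rate: float) -> RawRecording:
    """Anti-alias low-pass then integer decimation; onsets rescaled to the new rate."""
    factor = raw.sample_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        lower = raw.sample_rate / np.ceil(factor)
        raise ValidationError(
            f"target_rate {target_rate} is not an integer divisor of {raw.sample_rate}; "
            f"nearest valid rate: {lower:g} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return raw
    # zero-phase anti-alias low-pass at 0.8 x target Nyquist
    cutoff = 0.8 * (target_rate / 2.0)
    sos = scipy.signal.butter(8, cutoff, btype="low", fs=raw.sample_rate, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, raw.data, axis=1)
    data = np.ascontiguousarray(filtered[:, ::factor]).astype(raw.data.dtype, copy=False)
    events = [
        Event(int(round(e.onset_sample / factor)), e.label, e.sequence_index) for e in raw.events
    ]
    return RawRecording(
        subject_id=raw.subject_id,
        session_id=raw.session_id,
        block_id=raw.block_id,
        sample_rate=float(target_rate),
        channel_labels=list(raw.channel_labels),
        data=data,
        events=events,
    )


def segment(raw: RawRecording, tmin_ms: float = -200.0, tmax_ms: float = 1000.0) -> EpochedRecording:
    """Cut one epoch per event over the half-open window [tmin, tmax) ms."""
    offset = int(round(tmin_ms / 1000.0 * raw.sample_rate))
    n_samp = n_window_samples((tmin_ms, tmax_ms), raw.sample_rate)
    starts = np.array([e.onset_sample + offset for e in raw.events], dtype=np.int64)
    bad = [
        e for e, s in zip(raw.events, starts) if s < 0 or s + n_samp > raw.n_samples
    ]
    if bad:
        raise ValidationError(
            f"{len(bad)} epochs exceed recording bounds (first offending onset: "
            f"sample {bad[0].onset_sample})"
        )
    data = np.empty((len(starts), raw.n_channels, n_samp), dtype=raw.data.dtype)
    for i, s in enumerate(starts):
        data[i] = raw.data[:, s : s + n_samp]
    labels = np.array([e.label for e in raw.events], dtype=np.int8)
    return EpochedRecording(
        subject_id=raw.subject_id,
        session_id=raw.session_id,
        block_id=raw.block_id,
        data=data,
        labels=labels,
        sample_rate=raw.sample_rate,
        window_ms=(tmin_ms, tmax_ms),
        channel_labels=list(raw.channel_labels),
    )


def _replace_data(epochs: EpochedRecording, data: np.ndarray, **kw) -> EpochedRecording:
    fields = dict(
        subject_id=epochs.subject_id,
        session_id=epochs.session_id,
        block_id=epochs.block_id,
        data=data,
        labels=epochs.labels,
        sample_rate=epochs.sample_rate,
        window_ms=epochs.window_ms,
        channel_labels=list(epochs.channel_labels),
    )
    fields.update(kw)
    return EpochedRecording(**fields)


def bandpass(epochs: EpochedRecording, low_hz: float = 2.0, high_hz: float = 30.0) -> EpochedRecording:
    """Zero-phase 4th-order Butterworth band-pass, per trial and channel.

    Forward-backward filtering with reflective edge padding keeps symmetric
    waveforms symmetric (no phase distortion).
    """
    nyq = epochs.sample_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValidationError(
            f"invalid band [{low_hz}, {high_hz}] Hz for sample rate {epochs.sample_rate}"
        )
    sos = scipy.signal.butter(4, [low_hz, high_hz], btype="band", fs=epochs.sample_rate, output="sos")
    # the high-pass edge rings for seconds; reflect-pad long enough (~6 cycles
    # of the low edge) that truncation cannot break zero-phase symmetry
    pad = int(np.ceil(6.0 * epochs.sample_rate / low_hz))
    out = np.empty_like(epochs.data, dtype=float)
    chunk = max(1, int(2e7 // (epochs.n_channels * (epochs.n_samples + 2 * pad))))
    for i in range(0, epochs.n_trials, chunk):
        seg = np.pad(epochs.data[i : i + chunk].astype(float), ((0, 0), (0, 0), (pad, pad)), mode="symmetric")
        out[i : i + chunk] = scipy.signal.sosfiltfilt(sos, seg, axis=2, padlen=0)[:, :, pad:-pad]
    return _replace_data(epochs, out.astype(epochs.data.dtype, copy=False))


def rereference_car(epochs: EpochedRecording) -> EpochedRecording:
    """Common-average re-reference: subtract the instantaneous mean over channels."""
    if epochs.n_channels < 2:
        raise ValidationError("common-average reference needs >= 2 channels (would zero the data)")
    out = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return _replace_data(epochs, out.astype(epochs.data.dtype, copy=False))


def crop_window(epochs: EpochedRecording, start_ms: float, end_ms: float) -> EpochedRecording:
    """Restrict epochs to the half-open sub-window [start, end) ms."""
    w0, w1 = epochs.window_ms
    if start_ms < w0 or end_ms > w1 or start_ms >= end_ms:
        raise ValidationError(
            f"crop window [{start_ms}, {end_ms}) outside epoch window [{w0}, {w1})"
        )
    i0 = int(round((start_ms - w0) / 1000.0 * epochs.sample_rate))
    n = n_window_samples((start_ms, end_ms), epochs.sample_rate)
    out = np.ascontiguousarray(epochs.data[:, :, i0 : i0 + n])
    return _replace_data(epochs, out, window_ms=(start_ms, end_ms))


def baseline_correct(epochs: EpochedRecording, baseline_ms: tuple[float, float] | None = None) -> EpochedRecording:
    """Subtract each channel's mean over the baseline window (default: pre-trigger part)."""
    w0, w1 = epochs.window_ms
    if baseline_ms is None:
        baseline_ms = (w0, min(0.0, w1))
    b0, b1 = baseline_ms
    i0 = int(round((b0 - w0) / 1000.0 * epochs.sample_rate))
    i1 = int(round((b1 - w0) / 1000.0 * epochs.sample_rate))
    if i1 <= i0:
        raise ValidationError(f"empty baseline window {baseline_ms}")
    mean = epochs.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return _replace_data(epochs, (epochs.data - mean).astype(epochs.data.dtype, copy=False))


def preprocess_block(raw: RawRecording, params: PreprocessParams | None = None) -> EpochedRecording:
    """Full chain: downsample -> segment -> band-pass -> common-average reference.

    The analysis crop (e.g. [0, 500) ms) is applied later via :func:`crop_window`
    so the full epoch remains available.
    """
    if params is None:
        params = PreprocessParams()
    raw = downsample(raw, params.target_rate)
    if params.filter_continuous:
        sos = scipy.signal.butter(
            4, [params.band_low_hz, params.band_high_hz], btype="band", fs=raw.sample_rate, output="sos"
        )
        data = scipy.signal.sosfiltfilt(sos, raw.data, axis=1).astype(raw.data.dtype, copy=False)
        raw = dataclasses.replace(raw, data=data)
        epochs = segment(raw, params.epoch_tmin_ms, params.epoch_tmax_ms)
    else:
        epochs = segment(raw, params.epoch_tmin_ms, params.epoch_tmax_ms)
        epochs = bandpass(epochs, params.band_low_hz, params.band_high_hz)
    if params.car:
        epochs = rereference_car(epochs)
    if params.baseline_correct:
        epochs = baseline_correct(epochs)
    return epochs
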