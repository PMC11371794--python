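"""Preprocessing chain: decimation, segmentation, filtering, referencing, cropping."""

import numpy as np
import pytest

from cobci.core import Event, RawRecording, ValidationError
from cobci.preprocess import (
    PreprocessParams,
    bandpass,
    crop_window,
    downsample,
    preprocess_block,
    rereference_car,
    segment,
)


def make_raw(n_channels=3, n_samples=4000, sample_rate=1000.0, events=(), data=None, seed=0):
    if data is None:
        data = np.random.default_rng(seed).standard_normal((n_channels, n_samples))
    return RawRecording(
        subject_id="S01", session_id="sess1", block_id="block1",
        sample_rate=sample_rate, channel_labels=[f"ch{i}" for i in range(n_channels)],
        data=data, events=list(events),
    )


class TestDownsample:
    def test_factor_four(self):
        raw = make_raw(events=[Event(400, 1), Event(1200, 0)])
        out = downsample(raw, 250.0)
        assert out.sample_rate == 250.0
        assert out.n_samples == raw.n_samples // 4
        assert [e.onset_sample for e in out.events] == [100, 300]

    def test_identity_rate(self):
        raw = make_raw(events=[Event(3, 1)])
        out = downsample(raw, raw.sample_rate)
        assert out is raw

    def test_non_integer_factor_suggests_rate(self):
        raw = make_raw()
        with pytest.raises(ValidationError, match="nearest valid"):
            downsample(raw, 300.0)

    def test_sine_survives_decimation(self):
        """A 5 Hz sine keeps its spectral peak at 5 Hz after 1000 -> 250 Hz."""
        t = np.arange(4000) / 1000.0
        data = np.tile(np.sin(2 * np.pi * 5 * t), (2, 1))
        out = downsample(make_raw(n_channels=2, data=data), 250.0)
        spec = np.abs(np.fft.rfft(out.data[0]))
        freqs = np.fft.rfftfreq(out.n_samples, d=1 / 250.0)
        assert abs(freqs[np.argmax(spec)] - 5.0) <= freqs[1]


class TestSegment:
    def test_counts_and_window(self):
        events = [Event(i, 1 if i % 500 == 0 else 0) for i in range(300, 3600, 100)]
        raw = make_raw(sample_rate=250.0, events=events)
        ep = segment(raw, -200.0, 1000.0)
        assert ep.n_trials == len(events)
        assert ep.n_samples == 300  # 1.2 s at 250 Hz
        assert np.array_equal(ep.labels, [e.label for e in events])

    def test_epoch_equals_raw_slice(self):
        raw = make_raw(sample_rate=250.0, events=[Event(100, 1)])
        ep = segment(raw, -200.0, 1000.0)
        start = 100 + int(-200 / 1000 * 250)
        assert np.array_equal(ep.data[0], raw.data[:, start : start + 300])

    def test_empty_events(self):
        ep = segment(make_raw(), 0.0, 100.0)
        assert ep.n_trials == 0

    def test_out_of_bounds_listed(self):
        raw = make_raw(events=[Event(10, 1)])
        with pytest.raises(ValidationError, match="exceed"):
            segment(raw, -200.0, 1000.0)


class TestBandpass:
    def make_sine_epochs(self, freq, n_samples=250, sample_rate=250.0):
        t = np.arange(n_samples) / sample_rate
        data = np.tile(np.sin(2 * np.pi * freq * t), (2, 3, 1))
        return _epochs_with(data, sample_rate)

    def test_stopband_attenuation(self):
        ep = self.make_sine_epochs(50.0)
        out = bandpass(ep, 2.0, 30.0)
        mid = slice(50, 200)  # designed response, away from epoch-edge transients
        assert np.sqrt((out.data[..., mid] ** 2).mean()) <= 0.05 * np.sqrt((ep.data[..., mid] ** 2).mean())

    def test_dc_removed(self):
        ep = _epochs_with(np.full((2, 3, 250), 7.0), 250.0)
        out = bandpass(ep, 2.0, 30.0)
        assert np.abs(out.data).max() < 0.1

    def test_passband_preserved(self):
        ep = self.make_sine_epochs(10.0)
        out = bandpass(ep, 2.0, 30.0)
        mid = slice(50, 200)  # avoid edge transients
        in_amp = np.abs(ep.data[..., mid]).max()
        out_amp = np.abs(out.data[..., mid]).max()
        assert out_amp == pytest.approx(in_amp, rel=0.05)

    def test_invalid_band(self):
        ep = self.make_sine_epochs(10.0)
        with pytest.raises(ValidationError, match="band"):
            bandpass(ep, 30.0, 2.0)

    def test_zero_phase_keeps_pulse_symmetric(self):
        """Forward-backward filtering: a symmetric pulse stays symmetric."""
        n = 251
        t = np.arange(n)
        pulse = np.exp(-0.5 * ((t - n // 2) / 10.0) ** 2)
        ep = _epochs_with(np.tile(pulse, (1, 2, 1)), 250.0)
        out = bandpass(ep, 2.0, 30.0)
        y = out.data[0, 0]
        asym = np.abs(y - y[::-1]).max() / np.abs(y).max()
        assert asym <= 1e-6


class TestCAR:
    def test_constant_offset_zeroed(self):
        ep = _epochs_with(np.full((2, 4, 10), 3.3), 250.0)
        assert np.allclose(rereference_car(ep).data, 0.0)

    def test_two_channel_closed_form(self):
        a = np.arange(10.0)
        b = -2 * a + 1
        ep = _epochs_with(np.stack([a, b])[None], 250.0)
        out = rereference_car(ep)
        assert np.allclose(out.data[0, 0], (a - b) / 2)
        assert np.allclose(out.data[0, 1], (b - a) / 2)

    def test_channel_sums_zero_and_idempotent(self):
        ep = _epochs_with(np.random.default_rng(1).standard_normal((3, 5, 20)), 250.0)
        out = rereference_car(ep)
        assert np.abs(out.data.sum(axis=1)).max() < 1e-10
        again = rereference_car(out)
        assert np.allclose(again.data, out.data, atol=1e-12)

    def test_single_channel_rejected(self):
        ep = _epochs_with(np.ones((2, 1, 10)), 250.0)
        with pytest.raises(ValidationError, match="2 channels"):
            rereference_car(ep)


class TestCrop:
    def test_analysis_window_sample_count(self):
        ep = _epochs_with(np.random.default_rng(0).standard_normal((2, 3, 300)), 250.0,
                          window_ms=(-200.0, 1000.0))
        out = crop_window(ep, 0.0, 500.0)
        assert out.n_samples == 125
        assert out.window_ms == (0.0, 500.0)
        # contiguous slice of the original
        assert np.array_equal(out.data, ep.data[:, :, 50:175])

    def test_full_window_identity(self):
        ep = _epochs_with(np.random.default_rng(0).standard_normal((2, 3, 100)), 250.0)
        out = crop_window(ep, *ep.window_ms)
        assert np.array_equal(out.data, ep.data)

    def test_out_of_range(self):
        ep = _epochs_with(np.zeros((1, 2, 100)), 250.0)
        with pytest.raises(ValidationError, match="outside"):
            crop_window(ep, -100.0, 200.0)


class TestFullChain:
    def test_stagewise_equality(self):
        """preprocess_block equals the hand-composed stage pipeline."""
        events = [Event(i, 1 if i % 1000 == 0 else 0) for i in range(1000, 7000, 100)]
        raw = make_raw(n_channels=4, n_samples=9000, events=events, seed=3)
        params = PreprocessParams()
        auto = preprocess_block(raw, params)
        manual = rereference_car(
            bandpass(segment(downsample(raw, 250.0), -200.0, 1000.0), 2.0, 30.0)
        )
        assert auto == manual

    def test_shape_bookkeeping(self):
        events = [Event(i, 0) for i in range(1000, 5000, 100)]
        raw = make_raw(n_samples=7000, events=events)
        ep = preprocess_block(raw)
        assert ep.n_trials == len(events)
        assert ep.sample_rate == 250.0
        assert ep.n_samples == 300


def _epochs_with(data, sample_rate, window_ms=None):
    from cobci.core import EpochedRecording

    data = np.asarray(data, dtype=float)
    if window_ms is None:
        window_ms = (0.0, data.shape[2] / sample_rate * 1000.0)
    labels = np.zeros(data.shape[0], dtype=np.int8)
    if data.shape[0] > 1:
        labels[0] = 1
    return EpochedRecording(
        subject_id="S01", session_id="sess1", block_id="block1",
        data=data, labels=labels, sample_rate=sample_rate, window_ms=window_ms,
        channel_labels=[f"ch{i}" for i in range(data.shape[1])],
    )
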