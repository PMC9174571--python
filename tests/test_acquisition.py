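"""Sync alignment, filtering, pacing-spike detection and segmentation."""

import numpy as np
import pytest

from epibeat import acquisition as acq
from epibeat.simulate import (Channel, DeviceRecording,
                              MultiChannelRecording, PacingConfig)


def square_train(duration, fs, period=1.0, start=0.0, width=0.05,
                 skip=()):
    t = np.arange(int(duration * fs)) / fs
    x = np.zeros_like(t)
    k = 0
    while start + k * period < duration:
        if k not in skip:
            on = (t >= start + k * period) & (t < start + k * period + width)
            x[on] = 1.0
        k += 1
    return x


class TestSyncPulses:
    def test_ideal_train_onsets(self):
        x = square_train(10.0, 1000.0)
        onsets = acq.detect_sync_pulses(x, 1000.0)
        assert len(onsets) == 10
        np.testing.assert_allclose(onsets, np.arange(10), atol=1.5e-3)

    def test_flat_channel_empty(self):
        assert len(acq.detect_sync_pulses(np.zeros(1000), 1000.0)) == 0

    def test_missing_pulse_leaves_gap(self):
        x = square_train(10.0, 1000.0, skip={4})
        onsets = acq.detect_sync_pulses(x, 1000.0)
        assert len(onsets) == 9
        gaps = np.diff(onsets)
        assert gaps.max() == pytest.approx(2.0, abs=2e-3)

    def test_empty_channel_raises(self):
        with pytest.raises(ValueError):
            acq.detect_sync_pulses(np.array([]), 1000.0)


def two_device_recording(offset=0.25, skew_ppm=0.0, fs_a=2000.0,
                         fs_b=1000.0, duration=12.0):
    """Reference device plus a shifted/skewed second device, both seeing
    the same broadcast pulse train and a shared 7 Hz test tone."""
    rate = 1.0 + skew_ppm * 1e-6
    t_a = np.arange(int(duration * fs_a)) / fs_a
    n_b = int((duration - offset) * fs_b)
    t_b = offset + (np.arange(n_b) / fs_b) * rate

    def sync_at(t):
        phase = np.mod(t - 0.5, 1.0)
        return (((phase >= 0) & (phase < 0.05)) & (t >= 0.5)).astype(float)

    tone = lambda t: np.sin(2 * np.pi * 7.0 * t)  # noqa: E731
    dev_a = DeviceRecording("a", fs_a, {
        "sig_a": Channel(tone(t_a), fs_a, "au"),
        "sync": Channel(sync_at(t_a), fs_a, "V"),
    })
    dev_b = DeviceRecording("b", fs_b, {
        "sig_b": Channel(tone(t_b), fs_b, "au"),
        "sync": Channel(sync_at(t_b), fs_b, "V"),
    })
    return MultiChannelRecording({"a": dev_a, "b": dev_b}, "sync", {})


class TestAlignment:
    def test_recovers_static_offset(self):
        rec = two_device_recording(offset=0.25)
        al = acq.align_and_resample(rec)
        assert al.offset_applied["b"] == pytest.approx(0.25, abs=1e-3)
        assert al.offset_applied["a"] == pytest.approx(0.0, abs=1e-3)

    def test_identical_devices_zero_offset(self):
        rec = two_device_recording(offset=0.0, fs_b=2000.0)
        al = acq.align_and_resample(rec)
        assert abs(al.offset_applied["b"]) < 1e-3
        n = al.n_samples
        np.testing.assert_allclose(al.channels["sig_a"][: n],
                                   al.channels["sig_b"][: n], atol=1e-3)

    def test_clock_skew_residual_below_one_sample(self):
        rec = two_device_recording(offset=0.25, skew_ppm=50.0)
        al = acq.align_and_resample(rec)
        # After alignment the shared tone must coincide to sub-sample lag.
        a = al.channels["sig_a"]
        b = al.channels["sig_b"]
        lag = np.argmax(np.correlate(a - a.mean(), b - b.mean(), "full"))
        assert abs(lag - (len(b) - 1)) <= 1

    def test_aligned_channels_equal_length(self):
        rec = two_device_recording()
        al = acq.align_and_resample(rec)
        lengths = {len(c) for c in al.channels.values()}
        assert len(lengths) == 1

    def test_alignment_idempotent(self):
        rec = two_device_recording(offset=0.25, skew_ppm=50.0)
        al = acq.align_and_resample(rec)
        redone = MultiChannelRecording({
            "x": DeviceRecording("x", al.fs_common, {
                name: Channel(arr, al.fs_common, "au")
                for name, arr in al.channels.items()
            })
        }, "sync", {})
        al2 = acq.align_and_resample(redone)
        assert abs(al2.offset_applied["x"]) <= 1.0 / al.fs_common

    def test_missing_sync_channel(self):
        rec = two_device_recording()
        del rec.devices["b"].channels["sync"]
        with pytest.raises(acq.AlignmentError):
            acq.align_and_resample(rec)

    def test_ambiguous_offset_rejected(self):
        rec = two_device_recording(offset=2.2)
        with pytest.raises(acq.AlignmentError):
            acq.align_and_resample(rec)


class TestBandpass:
    fs = 2000.0

    def test_out_of_band_tone_attenuated_40db(self):
        t = np.arange(int(4 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 1.0 * t)
        y = acq.bandpass_filter(x, self.fs, "accel")
        core = slice(int(self.fs), int(3 * self.fs))
        assert np.abs(y[core]).max() < 10 ** (-40 / 20)

    def test_passband_tone_preserved_within_1db(self):
        t = np.arange(int(4 * self.fs)) / self.fs
        x = np.sin(2 * np.pi * 50.0 * t)
        y = acq.bandpass_filter(x, self.fs, "accel")
        core = slice(int(self.fs), int(3 * self.fs))
        assert np.abs(y[core]).max() > 10 ** (-1 / 20)

    def test_dc_removed(self):
        y = acq.bandpass_filter(np.full(4000, 3.7), self.fs, "accel")
        assert np.abs(y).max() < 1e-6 * 3.7

    def test_low_rate_rejected_for_accel_band(self):
        with pytest.raises(ValueError):
            acq.bandpass_filter(np.zeros(100), 400.0, "accel")


class TestPacingSpikes:
    def test_synthetic_ddd_recovers_av_delay(self, one_recording):
        rec, truth, pacing = one_recording
        al = acq.align_and_resample(rec)
        ecg = acq.bandpass_filter(al.channels["ecg"], al.fs_common, "ecg")
        a, v = acq.detect_pacing_spikes(ecg, al.fs_common, pacing)
        assert len(a) == len(v) > 10
        np.testing.assert_allclose(v - a, 0.150, atol=2e-3)
        # every detected atrial spike matches a true one within 2 ms
        for t in a + al.t0:
            assert np.min(np.abs(truth.beat_times - t)) < 2e-3

    def test_flat_ecg_empty(self):
        a, v = acq.detect_pacing_spikes(
            np.zeros(2000), 2000.0, PacingConfig("BiV", 150, 0))
        assert len(a) == 0 and len(v) == 0


class TestSegmentation:
    def make_aligned(self, n=12000, fs=2000.0):
        return acq.AlignedRecording(
            channels={"ecg": np.random.default_rng(0).normal(0, 1, n),
                      "acc": np.zeros(n)},
            fs_common=fs, t0=0.0, offset_applied={}, repairs=[],
        )

    def test_eleven_spikes_make_ten_beats(self):
        al = self.make_aligned()
        spikes = np.arange(11) * 0.5
        beats = acq.segment_beats(al, spikes, None, {"ecg": "ecg"})
        assert len(beats["ecg"]) == 10

    def test_constant_spacing_constant_length(self):
        al = self.make_aligned()
        spikes = np.arange(10) * 0.6
        beats = acq.segment_beats(al, spikes, None, {"ecg": "ecg"})
        lengths = {len(b.samples) for b in beats["ecg"]}
        assert lengths == {1200}

    def test_implausible_spacing_dropped(self):
        al = self.make_aligned()
        spikes = np.array([0.0, 0.6, 0.7, 1.3, 5.9])  # 0.1 s and 4.6 s gaps
        beats = acq.segment_beats(al, spikes, None, {"ecg": "ecg"})
        kept = {b.beat_index for b in beats["ecg"]}
        assert kept == {0, 2}

    def test_sample_conservation(self):
        """Kept beats plus logged drops and boundary regions tile the
        spike span exactly."""
        al = self.make_aligned()
        spikes = np.arange(9) * 0.6 + 0.3
        beats = acq.segment_beats(al, spikes, None, {"ecg": "ecg"})
        total = sum(len(b.samples) for b in beats["ecg"])
        span = int(round((spikes[-1] - spikes[0]) * al.fs_common))
        assert total == span

    def test_pressure_beats_single_systole(self, one_recording):
        rec, truth, pacing = one_recording
        al = acq.align_and_resample(rec)
        ecg = acq.bandpass_filter(al.channels["ecg"], al.fs_common, "ecg")
        a, _ = acq.detect_pacing_spikes(ecg, al.fs_common, pacing)
        pb = acq.segment_pressure_beats(al, a + al.t0)
        assert len(pb) >= len(a) - 3
        from scipy.signal import find_peaks
        for b in pb:
            peaks, _ = find_peaks(
                b.samples, height=b.samples.min() + 0.5 *
                (b.samples.max() - b.samples.min()),
                distance=int(0.1 * b.fs))
            assert len(peaks) == 1

    def test_needs_two_spikes(self):
        al = self.make_aligned()
        with pytest.raises(ValueError):
            acq.segment_beats(al, np.array([0.5]), None, {"ecg": "ecg"})
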