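"""Re-referencing, FIR filtering, downsampling, interpolation, epoching."""

import numpy as np
import pytest

from miadapt import (
    Recording,
    bandpass_fir,
    downsample,
    extract_epochs,
    rereference_average,
    select_and_interpolate,
)
from miadapt.preprocess import denoise_hook, fir_order


def make_rec(data, fs=1000.0, names=None, events=()):
    names = names or tuple(f"ch{i}" for i in range(len(data)))
    return Recording(np.asarray(data, float), names, fs, list(events))


class TestRereference:
    def test_channel_mean_zero(self, rng):
        rec = make_rec(rng.standard_normal((6, 500)))
        out = rereference_average(rec)
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        rec = make_rec(rng.standard_normal((4, 200)))
        once = rereference_average(rec)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data)

    def test_two_channel_closed_form(self):
        a = np.sin(np.linspace(0, 5, 100))
        b = np.cos(np.linspace(0, 5, 100))
        out = rereference_average(make_rec([a, b]))
        assert np.allclose(out.data[0], (a - b) / 2)
        assert np.allclose(out.data[1], (b - a) / 2)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="single"):
            rereference_average(make_rec(np.zeros((1, 10))))


class TestBandpass:
    def test_order_rule(self):
        assert fir_order(1000.0, 1.0) == 3000
        assert fir_order(250.0, 1.0) == 750  # odd product rounds to even
        assert fir_order(1000.0, 7.0) == 428

    def test_passband_amplitude_preserved(self):
        fs, f = 1000.0, 10.0
        t = np.arange(int(10 * fs)) / fs
        rec = make_rec([np.sin(2 * np.pi * f * t)], fs=fs)
        out = bandpass_fir(rec, 1.0, 40.0).data[0]
        steady = out[int(2 * fs) : int(8 * fs)]
        amp = steady.max()
        assert abs(amp - 1.0) < 0.05

    def test_stopband_attenuation(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        rec = make_rec([np.sin(2 * np.pi * 50.0 * t)], fs=fs)
        out = bandpass_fir(rec, 1.0, 40.0).data[0]
        rms_in = np.sqrt(np.mean(rec.data[0] ** 2))
        rms_out = np.sqrt(np.mean(out[int(2 * fs) : int(8 * fs)] ** 2))
        assert rms_out < 0.10 * rms_in

    def test_invalid_edges(self):
        rec = make_rec(np.zeros((2, 100)), fs=100.0)
        for lo, hi in [(0.0, 40.0), (45.0, 40.0), (1.0, 60.0)]:
            with pytest.raises(ValueError):
                bandpass_fir(rec, lo, hi)

    def test_commutes_with_rereference(self, rng):
        rec = make_rec(rng.standard_normal((4, 4000)))
        a = bandpass_fir(rereference_average(rec), 1.0, 40.0).data
        b = rereference_average(bandpass_fir(rec, 1.0, 40.0)).data
        assert np.allclose(a, b, atol=1e-9)


class TestDownsample:
    def test_ratio_four(self, rng):
        rec = make_rec(rng.standard_normal((2, 4000)), fs=1000.0,
                       events=[(100, "a"), (2000, "b")])
        out = downsample(rec, 250.0)
        assert out.data.shape == (2, 1000)
        assert out.fs == 250.0
        assert out.events == [(25, "a"), (500, "b")]

    def test_identity(self, rng):
        rec = make_rec(rng.standard_normal((2, 400)), fs=250.0)
        out = downsample(rec, 250.0)
        assert np.array_equal(out.data, rec.data)

    def test_spectral_peak_preserved(self):
        fs = 1000.0
        t = np.arange(int(8 * fs)) / fs
        rec = make_rec([np.sin(2 * np.pi * 20.0 * t)], fs=fs)
        out = downsample(rec, 250.0).data[0]
        freqs = np.fft.rfftfreq(len(out), 1 / 250.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(out)))]
        assert abs(peak - 20.0) < 0.2

    def test_non_integer_ratio_rejected(self, rng):
        rec = make_rec(rng.standard_normal((2, 400)), fs=1000.0)
        with pytest.raises(ValueError, match="integer"):
            downsample(rec, 300.0)


class TestSelectInterpolate:
    def test_selection_order(self, rng):
        names = ("C3", "C4", "Cz", "CP3", "CP4")
        rec = make_rec(rng.standard_normal((5, 100)), names=names)
        out = select_and_interpolate(rec, keep=("CP4", "C3"))
        assert out.channel_names == ("CP4", "C3")
        assert np.array_equal(out.data[0], rec.data[4])
        assert np.array_equal(out.data[1], rec.data[0])

    def test_no_bad_is_pure_selection(self, rng):
        names = ("C3", "C4", "Cz")
        rec = make_rec(rng.standard_normal((3, 50)), names=names)
        out = select_and_interpolate(rec, keep=names, bad=())
        assert np.array_equal(out.data, rec.data)

    def test_interpolation_of_common_sinusoid(self):
        """Neighbors carrying an identical signal reproduce it exactly at
        the interpolated site (weights sum to one)."""
        names = ("C3", "C1", "C5", "FC3", "CP3", "Cz")
        sine = np.sin(np.linspace(0, 10, 300))
        data = np.tile(sine, (6, 1))
        rec = make_rec(data, names=names)
        out = select_and_interpolate(rec, keep=names, bad=("C3",))
        assert np.allclose(out.data[0], sine, atol=1e-12)

    def test_bad_not_in_keep_warns(self, rng):
        names = ("C3", "C4", "Cz")
        rec = make_rec(rng.standard_normal((3, 50)), names=names)
        with pytest.warns(UserWarning, match="skipped"):
            out = select_and_interpolate(rec, keep=("C3", "C4"), bad=("Pz",))
        assert out.channel_names == ("C3", "C4")

    def test_missing_keep_channel_rejected(self, rng):
        rec = make_rec(rng.standard_normal((2, 50)), names=("C3", "C4"))
        with pytest.raises(ValueError, match="absent"):
            select_and_interpolate(rec, keep=("C3", "Oz"))


class TestExtractEpochs:
    def make_recording(self, n_trials=10, fs=250.0, seed=0):
        rng = np.random.default_rng(seed)
        dur = 5.0
        n = int(n_trials * dur * fs)
        data = rng.standard_normal((3, n))
        events = [(int(i * dur * fs), "left_hand" if i % 2 else "right_hand")
                  for i in range(n_trials)]
        return Recording(data, ("C3", "C4", "Cz"), fs, events)

    def test_window_sampling(self):
        rec = self.make_recording()
        ep = extract_epochs(rec, window=(1.0, 3.0))
        assert ep.n_samples == 750
        assert ep.fs == 250.0

    def test_retention_counts(self):
        rec = self.make_recording(n_trials=20)
        ep = extract_epochs(rec, window=(1.0, 3.0), per_task_keep=7)
        assert ep.n_epochs == 14
        labels, counts = np.unique(ep.labels, return_counts=True)
        assert dict(zip(labels, counts)) == {"left_hand": 7, "right_hand": 7}

    def test_retention_prefers_low_amplitude(self):
        rec = self.make_recording(n_trials=4)
        # blow up one trial's amplitude; it must be dropped first
        onset = rec.events[0][0]
        rec.data[:, onset : onset + 1250] *= 50
        ep = extract_epochs(rec, window=(1.0, 3.0), per_task_keep=1)
        assert np.abs(ep.data).max() < 25

    def test_window_outside_recording_rejected(self):
        rec = self.make_recording(n_trials=2)
        with pytest.raises(ValueError, match="outside"):
            extract_epochs(rec, window=(4.0, 3.0))

    def test_insufficient_trials_names_task(self):
        rec = self.make_recording(n_trials=4)
        with pytest.raises(ValueError, match="left_hand|right_hand"):
            extract_epochs(rec, window=(1.0, 3.0), per_task_keep=3)

    def test_deterministic(self):
        rec = self.make_recording()
        a = extract_epochs(rec, window=(1.0, 3.0), per_task_keep=4)
        b = extract_epochs(rec, window=(1.0, 3.0), per_task_keep=4)
        assert np.array_equal(a.data, b.data)


def test_denoise_hook_passthrough_and_plugin(rng):
    rec = make_rec(rng.standard_normal((2, 50)))
    assert denoise_hook(rec) is rec
    flipped = denoise_hook(rec, hook=lambda r: r.copy_with(data=-r.data))
    assert np.array_equal(flipped.data, -rec.data)
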