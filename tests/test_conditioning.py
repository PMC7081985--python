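"""Signal conditioning: filters, line noise, resampling, epochs, spikes."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from vocolock.conditioning import (
    EpochSet,
    NeuralRecording,
    bandpass_lfp,
    best_frequency,
    detect_spikes,
    downsample,
    extract_epochs,
    psth,
    read_spike_csv,
    remove_line_noise,
    write_spike_csv,
    zscore_by_structure,
    zscore_recording,
)
from vocolock.vocal import CallEvent


def _rec(traces, fs=1000.0, structures=None):
    traces = np.atleast_2d(traces)
    n = traces.shape[0]
    structures = structures or ["FAF"] * n
    meta = pd.DataFrame(
        {"structure": structures, "depth_um": 50.0 * (np.arange(n) + 1)}
    )
    return NeuralRecording(traces=traces, fs_hz=fs, channel_meta=meta)


def _tone(freq, fs=1000.0, dur=4.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        out = bandpass_lfp(_rec(_tone(6.0))).traces[0]
        mid = slice(1000, 3000)
        assert np.max(np.abs(out[mid])) == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation(self):
        out = bandpass_lfp(_rec(_tone(200.0))).traces[0]
        assert np.max(np.abs(out[1000:3000])) < 0.1  # >= 10x reduction

    def test_dc_removed(self):
        out = bandpass_lfp(_rec(np.full(4000, 3.0))).traces[0]
        assert np.mean(np.abs(out)) < 0.03

    def test_nonfinite_rejected(self):
        x = _tone(6.0)
        x[10] = np.nan
        with pytest.raises(ValueError):
            bandpass_lfp(_rec(x))


def _peak_power_at(x, fs, freq):
    f, pxx = signal.periodogram(x, fs=fs)
    return pxx[np.argmin(np.abs(f - freq))]


class TestLineNoise:
    def test_contaminated_tone_reduced_10db(self, rng):
        fs = 1000.0
        x = rng.standard_normal(8000) + 3 * _tone(50.0, fs, 8.0)
        rec = _rec(x, fs)
        out = remove_line_noise(rec).traces[0]
        before = _peak_power_at(x, fs, 50.0)
        after = _peak_power_at(out, fs, 50.0)
        assert 10 * np.log10(before / after) >= 10

    def test_clean_noise_rms_preserved(self, rng):
        x = rng.standard_normal(8000)
        out = remove_line_noise(_rec(x)).traces[0]
        rms_in, rms_out = np.std(x), np.std(out)
        assert abs(rms_out - rms_in) / rms_in < 0.01

    def test_pure_tone_mostly_removed(self):
        x = _tone(50.0, dur=8.0)
        out = remove_line_noise(_rec(x)).traces[0]
        assert np.sqrt(np.mean(out**2)) < 0.1 * np.sqrt(np.mean(x**2))

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError, match="two line cycles"):
            remove_line_noise(_rec(_tone(50.0)), win_s=0.03)


class TestDownsample:
    def test_tone_preserved(self):
        fs = 20_000.0
        rec = _rec(_tone(30.0, fs, 2.0), fs)
        out = downsample(rec, 1000.0)
        assert out.fs_hz == 1000.0
        assert out.traces.shape[1] == 2000
        mid = out.traces[0][500:1500]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.02)

    def test_alias_suppressed(self):
        fs = 20_000.0
        out = downsample(_rec(_tone(700.0, fs, 2.0), fs), 1000.0)
        assert np.max(np.abs(out.traces[0][200:1800])) < 0.1  # >= 20 dB

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            downsample(_rec(_tone(30.0, 1500.0), 1500.0), 1000.0)


class TestZScore:
    def test_per_channel_moments(self, rng):
        rec = _rec(rng.standard_normal((3, 5000)) * [[1], [2], [5]])
        out = zscore_recording(rec, "per_channel")
        assert np.allclose(out.traces.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(out.traces.std(axis=1), 1, atol=1e-9)

    def test_across_channels_preserves_ratio(self, rng):
        rec = _rec(np.vstack([rng.standard_normal(20000),
                              2.0 * rng.standard_normal(20000)]))
        out = zscore_recording(rec, "across_channels")
        ratio = out.traces[1].std() / out.traces[0].std()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_constant_channel_named_in_error(self, rng):
        rec = _rec(np.vstack([rng.standard_normal(1000), np.ones(1000)]))
        with pytest.raises(ValueError, match="channel 1"):
            zscore_recording(rec, "per_channel")

    def test_by_structure_modes(self, rng):
        rec = _rec(rng.standard_normal((4, 20000)) * [[1], [3], [1], [2]],
                   structures=["FAF", "FAF", "CN", "CN"])
        out = zscore_by_structure(rec)
        # FAF keeps relative amplitudes, CN channels individually unit-std
        assert out.traces[1].std() / out.traces[0].std() == pytest.approx(3.0, rel=0.1)
        assert out.traces[2].std() == pytest.approx(1.0, rel=1e-6)
        assert out.traces[3].std() == pytest.approx(1.0, rel=1e-6)


class TestExtractEpochs:
    def test_alignment_sample(self):
        fs = 1000.0
        x = np.arange(5000, dtype=float)
        rec = _rec(x, fs)
        ev = CallEvent(onset_s=2.0, offset_s=2.01)
        eps = extract_epochs(rec, [ev])
        assert eps.data.shape == (1, 1, 1001)
        assert eps.data[0, 0, 500] == x[2000]
        assert eps.time[500] == 0.0

    def test_no_events_empty(self):
        eps = extract_epochs(_rec(np.zeros(3000)), [])
        assert eps.n_trials == 0

    def test_out_of_bounds_skipped_with_warning(self):
        rec = _rec(np.zeros(10_000))
        with pytest.warns(UserWarning, match="skipped"):
            eps = extract_epochs(rec, [CallEvent(onset_s=0.1, offset_s=0.11)])
        assert eps.n_trials == 0

    def test_hdf5_roundtrip(self, tmp_path, rng):
        rec = _rec(rng.standard_normal((2, 4000)), structures=["FAF", "CN"])
        events = [CallEvent(onset_s=1.0, offset_s=1.01, class_label="echolocation")]
        eps = extract_epochs(rec, events)
        eps.to_hdf5(tmp_path / "e.h5")
        back = EpochSet.from_hdf5(tmp_path / "e.h5")
        assert np.array_equal(back.data, eps.data)
        assert list(back.labels["class"]) == ["echolocation"]


class TestDetectSpikes:
    def _noise_with_spikes(self, rng, n_spikes=50, amp_mads=12.0, fs=20_000.0,
                           dur=10.0):
        x = rng.standard_normal(int(dur * fs))
        filt = signal.sosfiltfilt(
            signal.butter(2, [300, 3000], btype="bandpass", fs=fs, output="sos"), x
        )
        mad = np.median(np.abs(filt - np.median(filt))) / 0.6745
        times = np.sort(rng.uniform(0.1, dur - 0.1, n_spikes))
        times = times[np.concatenate([[True], np.diff(times) > 5e-3])]
        wave = -amp_mads * mad * signal.windows.gaussian(int(0.6e-3 * fs), int(0.1e-3 * fs))
        for t in times:
            j = int(t * fs) - wave.size // 2
            x[j : j + wave.size] += wave
        return _rec(x, fs), times

    def test_injected_spikes_recovered(self, rng):
        rec, times = self._noise_with_spikes(rng)
        det = detect_spikes(rec)[0]
        hits = sum(np.min(np.abs(det.times_s - t)) < 0.2e-3 for t in times)
        assert hits >= len(times) - 1

    def test_false_positive_rate_on_noise(self, rng):
        rec = _rec(rng.standard_normal(200_000), 20_000.0)
        det = detect_spikes(rec)[0]
        assert det.times_s.size / 10.0 < 1.0  # < 1 Hz over 10 s

    def test_refractory_lockout(self):
        fs = 20_000.0
        x = 0.01 * np.sin(2 * np.pi * 500 * np.arange(int(fs)) / fs)
        wave = -signal.windows.gaussian(12, 2)
        for t in (0.5, 0.5003):  # 0.3 ms apart
            j = int(t * fs)
            x[j : j + wave.size] += wave
        det = detect_spikes(_rec(x, fs))[0]
        near = det.times_s[(det.times_s > 0.499) & (det.times_s < 0.502)]
        assert near.size == 1

    def test_scale_invariance(self, rng):
        rec, _ = self._noise_with_spikes(rng, n_spikes=20)
        a = detect_spikes(rec)[0].times_s
        rec5 = _rec(5.0 * rec.traces[0], rec.fs_hz)
        b = detect_spikes(rec5)[0].times_s
        assert np.array_equal(a, b)

    def test_spike_csv_roundtrip(self, tmp_path, rng):
        rec, _ = self._noise_with_spikes(rng, n_spikes=10)
        trains = detect_spikes(rec)
        write_spike_csv(trains, tmp_path / "s.csv")
        back = read_spike_csv(tmp_path / "s.csv")
        assert np.allclose(back[0].times_s, trains[0].times_s)


class TestPSTH:
    def test_single_bin_spike(self):
        onsets = np.arange(10, dtype=float) * 2 + 1
        centers, rate = psth(onsets, onsets)  # one spike exactly at each onset
        hot = np.flatnonzero(rate)
        assert hot.size == 1  # all spikes land in the single bin containing 0
        assert abs(centers[hot[0]]) <= 0.0015
        assert rate[hot[0]] == pytest.approx(1.0)

    def test_homogeneous_poisson_rate(self, rng):
        r = 40.0
        spikes = np.sort(rng.uniform(0, 400, int(400 * r)))
        onsets = np.arange(1.0, 399.0, 2.0)
        _, rate = psth(spikes, onsets)
        assert rate.mean() == pytest.approx(r * 0.003, rel=0.1)

    def test_empty_trains_zero(self):
        _, rate = psth(np.empty(0), np.array([5.0]))
        assert np.all(rate == 0)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            psth(np.array([1.0]), np.empty(0))


class TestBestFrequency:
    def _epochs(self, responsive_khz, probe_khz, rng, gain=1.0):
        time = np.arange(-100, 201) / 1000.0
        out = {}
        for f in probe_khz:
            data = 0.05 * rng.standard_normal((5, 2, time.size))
            if f == responsive_khz:
                resp = gain * np.exp(-np.clip(time, 0, None) / 0.05) * (time > 0)
                data[:, 0, :] += resp
            out[f] = data
        return out, time

    def test_responsive_channel(self, rng):
        grid = list(range(10, 95, 5))
        epochs, time = self._epochs(15, grid, rng)
        freqs, best, tuning = best_frequency(epochs, 1000.0, time)
        assert best[0] == 15

    def test_flat_tie_to_lowest(self, rng):
        epochs = {f: np.zeros((3, 1, 301)) for f in (10, 20, 30)}
        time = np.arange(-100, 201) / 1000.0
        _, best, _ = best_frequency(epochs, 1000.0, time)
        assert best[0] == 10

    def test_scale_invariance(self, rng):
        grid = [10, 15, 20]
        e1, time = self._epochs(15, grid, rng, gain=1.0)
        rng2 = np.random.default_rng(12345)
        e2, _ = self._epochs(15, grid, rng2, gain=2.0)
        _, b1, _ = best_frequency(e1, 1000.0, time)
        _, b2, _ = best_frequency(e2, 1000.0, time)
        assert b1[0] == b2[0] == 15


def test_processing_commutes_with_epoching(rng):
    """Filter+downsample then epoch == wide-epoch then process, mid-window."""
    fs = 4000.0
    x = rng.standard_normal(int(16 * fs))
    rec = _rec(x, fs)
    processed = downsample(bandpass_lfp(rec), 1000.0)
    ev = CallEvent(onset_s=8.0, offset_s=8.01)
    direct = extract_epochs(processed, [ev]).data[0, 0]
    wide = _rec(x[int(2.0 * fs) : int(14.0 * fs)], fs)  # epoch-first, +/-6 s
    wide_proc = downsample(bandpass_lfp(wide), 1000.0).traces[0]
    center = wide_proc[5500:6501]  # t = 8 s sits at sample 6000 of the cut
    rms = np.sqrt(np.mean((direct - center) ** 2))
    assert rms < 1e-6
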