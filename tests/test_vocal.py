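"""Call detection, spectral characterization and isolation selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocolock.synth import (
    COMMUNICATION_LF_SPEC,
    ECHOLOCATION_SPEC,
    generate_call_audio,
)
from vocolock.vocal import (
    CallEvent,
    CallSpectrum,
    call_spectrogram,
    classify_call,
    detect_calls,
    denoised_spectrum,
    events_to_frame,
    frame_to_events,
    peak_frequency,
    select_isolated,
    subclassify_communication,
)

FS = 250_000.0


def _track_with_pulses(onsets_s, duration_s, rng, spec=ECHOLOCATION_SPEC):
    track = 1e-4 * rng.standard_normal(int(duration_s * FS))
    for onset in onsets_s:
        core, _ = generate_call_audio(spec, FS, rng, pad_s=0.0, noise_level=0.0)
        j = int(round(onset * FS))
        track[j : j + core.size] += core
    return track


class TestDetectCalls:
    def test_two_pulses_one_second_apart(self, rng):
        onsets = [0.5, 1.5]
        track = _track_with_pulses(onsets, 2.5, rng)
        events = detect_calls(track, FS)
        assert len(events) == 2
        for ev, onset in zip(events, onsets):
            assert abs(ev.onset_s - onset) < 0.5e-3

    def test_pure_noise_yields_no_events(self, rng):
        assert detect_calls(1e-4 * rng.standard_normal(100_000), FS) == []

    def test_subthreshold_dip_is_merged(self):
        fs = 100_000.0
        t = np.arange(int(0.01 * fs)) / fs
        x = np.sin(2 * np.pi * 20_000 * t)
        mid = x.size // 2
        dip = int(0.1e-3 * fs)
        x[mid : mid + dip] = 0.0
        events = detect_calls(x, fs, threshold=0.1, min_gap_ms=1.0)
        assert len(events) == 1


class TestCallSpectrogram:
    def test_pure_tone_ridge(self):
        t = np.arange(int(0.005 * FS)) / FS
        m = call_spectrogram(np.sin(2 * np.pi * 72_000 * t), FS)
        ridge = m.freq[np.argmax(m.values, axis=0)]
        assert np.allclose(ridge, 72_000, atol=FS / 2048)
        assert np.isclose(np.median(np.diff(m.time)), 0.05e-3 * (12 / 12.5), rtol=0.1)

    def test_down_sweep_ridge_decreases(self):
        t = np.arange(int(0.005 * FS)) / FS
        finst = 90_000 - (30_000 / t[-1]) * t
        x = np.sin(2 * np.pi * np.cumsum(finst) / FS)
        m = call_spectrogram(x, FS)
        ridge = m.freq[np.argmax(m.values, axis=0)]
        inner = ridge[3:-3]
        assert np.all(np.diff(inner) <= FS / 2048 + 1)  # monotone within a bin
        assert inner[0] - inner[-1] > 20_000

    def test_dc_input_power_at_zero_frequency(self):
        m = call_spectrogram(np.ones(1000), FS)
        # zero-padding spreads the window mainlobe over a couple of bins
        assert np.all(m.freq[np.argmax(m.values, axis=0)] <= 2 * FS / 2048)
        low = m.freq < 2000
        assert m.values[low].sum() / m.values.sum() > 0.99

    def test_short_waveform_single_frame(self):
        m = call_spectrogram(np.ones(20), FS)
        assert m.time.size == 1


class TestPeakFrequency:
    def test_tone_in_noise(self, rng):
        t = np.arange(5000) / FS
        noise = 0.05 * rng.standard_normal(t.size)
        call = np.sin(2 * np.pi * 14_000 * t) + 0.05 * rng.standard_normal(t.size)
        pk = peak_frequency(call, noise, FS)
        assert abs(pk - 14.0) <= FS / t.size / 1e3  # within one FFT bin

    def test_exact_cancellation_flagged(self, rng):
        x = rng.standard_normal(1000)
        assert np.isnan(peak_frequency(x, x, FS))

    def test_tie_breaks_to_lower_frequency(self):
        t = np.arange(5000) / FS
        x = np.sin(2 * np.pi * 20_000 * t) + np.sin(2 * np.pi * 60_000 * t)
        pk = peak_frequency(x, np.zeros_like(x), FS)
        assert pk == pytest.approx(20.0, abs=0.1)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_amplitude_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        t = np.arange(2000) / FS
        call = np.sin(2 * np.pi * 30_000 * t) + 0.1 * rng.standard_normal(t.size)
        noise = 0.1 * rng.standard_normal(t.size)
        assert peak_frequency(call, noise, FS) == peak_frequency(
            scale * call, scale * noise, FS
        )


class TestClassification:
    @pytest.mark.parametrize(
        "peak,expected",
        [(72.0, "echolocation"), (14.0, "communication"), (50.0, "communication")],
    )
    def test_class_boundary(self, peak, expected):
        assert classify_call(peak) == expected

    def test_undefined_peak_rejected(self):
        with pytest.raises(ValueError):
            classify_call(float("nan"))

    @pytest.mark.parametrize("h,l,expected", [(6, 10, "LHF"), (4, 10, "LF"), (5, 10, "LHF")])
    def test_lhf_rule(self, h, l, expected):
        spec = CallSpectrum(
            freq_khz=np.array([14.0, 60.0]), power=np.array([l, h], float),
            denoised=True,
        )
        assert subclassify_communication(spec) == expected

    def test_empty_high_band_is_lf(self):
        spec = CallSpectrum(freq_khz=np.array([10.0, 20.0]),
                            power=np.array([3.0, 1.0]), denoised=True)
        assert subclassify_communication(spec) == "LF"

    def test_generated_classes_recovered(self, rng):
        for spec, expected in [(ECHOLOCATION_SPEC, "echolocation"),
                               (COMMUNICATION_LF_SPEC, "communication")]:
            wave, ev = generate_call_audio(spec, FS, rng)
            i0 = int(ev.onset_s * FS)
            i1 = int(ev.offset_s * FS)
            n = i1 - i0
            noise = 1e-3 * rng.standard_normal(n)
            pk = peak_frequency(wave[i0:i1], noise, FS)
            assert classify_call(pk) == expected


def _events(onsets, dur=0.005):
    return [CallEvent(onset_s=o, offset_s=o + dur) for o in onsets]


class TestSelectIsolated:
    def test_direct_rule(self):
        flagged = select_isolated(_events([1.0, 1.3, 3.0]), recording_bounds=(0, 5))
        assert [e.isolated for e in flagged] == [False, False, True]

    def test_contaminated_post_flag(self):
        flagged = select_isolated(_events([3.0, 3.2]), recording_bounds=(0, 10))
        assert flagged[0].contaminated_post and not flagged[0].isolated
        assert not flagged[1].contaminated_post

    def test_start_margin(self):
        flagged = select_isolated(_events([0.2]), recording_bounds=(0, 10))
        assert not flagged[0].isolated

    @given(
        onsets=st.lists(
            st.floats(min_value=0.6, max_value=30.0), min_size=1, max_size=8,
            unique=True,
        )
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_idempotent_and_order_independent(self, onsets):
        events = _events(sorted(onsets))
        once = select_isolated(events, recording_bounds=(0, 40))
        twice = select_isolated(once, recording_bounds=(0, 40))
        assert [(e.isolated, e.contaminated_post) for e in once] == [
            (e.isolated, e.contaminated_post) for e in twice
        ]
        perm = select_isolated(events[::-1], recording_bounds=(0, 40))
        assert {(e.onset_s, e.isolated) for e in perm} == {
            (e.onset_s, e.isolated) for e in once
        }


def test_event_csv_roundtrip(tmp_path):
    events = select_isolated(_events([1.0, 3.0]), recording_bounds=(0, 5))
    events[0].class_label = "communication"
    events[0].subclass = "LHF"
    df = events_to_frame(events)
    back = frame_to_events(df)
    assert back[0].class_label == "communication"
    assert back[0].subclass == "LHF"
    assert back[1].isolated == events[1].isolated
    assert back[0].onset_s == pytest.approx(1.0)
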