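"""Randomization trials, multitaper spectrograms, Cliff's Delta maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocolock.spectral import (
    TimeFrequencyMap,
    band_depth_profile,
    build_randomization_trials,
    cliffs_delta,
    cliffs_delta_nd,
    effect_size_map,
    multitaper_spectrogram,
)

MT_FAST = dict(fs=1000.0, step_s=0.005, nfft=512, time_offset_s=-0.5)


class TestRandomizationTrials:
    def test_identical_epochs_average_to_epoch(self, rng):
        epoch = rng.standard_normal(200)
        epochs = np.tile(epoch, (30, 1))
        rt = build_randomization_trials(epochs, n_rand=20, k=10, rng=0)
        assert np.allclose(rt.trials, epoch)

    def test_clt_scaling_of_trial_std(self, rng):
        epochs = rng.standard_normal((2000, 50))
        rt = build_randomization_trials(epochs, n_rand=400, k=100, rng=1)
        per_sample_std = rt.trials.std(axis=0).mean()
        assert per_sample_std == pytest.approx(0.1, rel=0.2)

    def test_mean_converges_to_grand_mean(self, rng):
        epochs = rng.standard_normal((50, 40)) + 2.0
        rt = build_randomization_trials(epochs, n_rand=3000, k=10, rng=2)
        assert np.allclose(rt.trials.mean(axis=0), epochs.mean(axis=0), atol=0.05)

    def test_seed_reproducible(self, rng):
        epochs = rng.standard_normal((40, 30))
        a = build_randomization_trials(epochs, n_rand=50, k=10, rng=7)
        b = build_randomization_trials(epochs, n_rand=50, k=10, rng=7)
        assert np.array_equal(a.trials, b.trials)

    def test_oversampling_warns(self, rng):
        epochs = rng.standard_normal((5, 10))
        with pytest.warns(UserWarning, match="replacement"):
            build_randomization_trials(epochs, n_rand=10, k=8, rng=0)

    @pytest.mark.parametrize("n_rand,k", [(0, 10), (10, 0)])
    def test_invalid_counts_rejected(self, n_rand, k):
        with pytest.raises(ValueError):
            build_randomization_trials(np.zeros((10, 5)), n_rand=n_rand, k=k)


class TestMultitaper:
    def test_sinusoid_peak_within_bandwidth(self):
        t = np.arange(1000) / 1000.0
        m = multitaper_spectrogram(np.sin(2 * np.pi * 40 * t), step_s=0.05)
        peak_f = m.freq[np.argmax(m.values.mean(axis=1))]
        assert abs(peak_f - 40) <= 8.0  # TW/win = 8 Hz bandwidth

    def test_white_noise_flat(self, rng):
        vals = []
        for _ in range(20):
            m = multitaper_spectrogram(rng.standard_normal(1000), step_s=0.05,
                                       fmin=10, fmax=80)
            vals.append(m.values.mean(axis=1))
        spectrum = np.mean(vals, axis=0)
        db = 10 * np.log10(spectrum / spectrum.mean())
        assert np.all(np.abs(db) < 3)

    def test_zero_signal_zero_map(self):
        m = multitaper_spectrogram(np.zeros(1000), step_s=0.05)
        assert np.all(m.values == 0)

    def test_too_many_tapers_rejected(self):
        with pytest.raises(ValueError, match="2\\*TW-1"):
            multitaper_spectrogram(np.zeros(1000), TW=2, K=4)

    def test_amplitude_squared_scaling(self):
        t = np.arange(1000) / 1000.0
        peaks = []
        for amp in (1, 2, 4):
            m = multitaper_spectrogram(amp * np.sin(2 * np.pi * 40 * t), step_s=0.05)
            peaks.append(m.values.max())
        assert peaks[1] / peaks[0] == pytest.approx(4.0, rel=1e-3)
        assert peaks[2] / peaks[1] == pytest.approx(4.0, rel=1e-3)


class TestCliffsDelta:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([2, 3], [0, 1], 1.0),
            ([1, 2, 3], [2, 3, 4], -5.0 / 9.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert cliffs_delta(a, b) == pytest.approx(expected, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])

    @given(
        a=st.lists(st.integers(0, 6), min_size=1, max_size=10),
        b=st.lists(st.integers(0, 6), min_size=1, max_size=10),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_antisymmetry_and_monotone_invariance(self, a, b):
        d = cliffs_delta(a, b)
        assert d == pytest.approx(-cliffs_delta(b, a), abs=1e-12)
        f = lambda x: np.exp(np.asarray(x, float))  # strictly monotone
        assert cliffs_delta(f(a), f(b)) == pytest.approx(d, abs=1e-12)
        assert -1.0 <= d <= 1.0

    def test_nd_matches_scalar(self, rng):
        a = rng.integers(0, 5, size=(12, 4, 3)).astype(float)
        b = rng.integers(0, 5, size=(9, 4, 3)).astype(float)
        d = cliffs_delta_nd(a, b)
        for i in range(4):
            for j in range(3):
                assert d[i, j] == pytest.approx(cliffs_delta(a[:, i, j], b[:, i, j]),
                                                abs=1e-12)


class TestEffectSizeMap:
    def test_identical_trial_sets_near_zero(self, rng):
        trials = rng.standard_normal((150, 1001))
        em = effect_size_map(trials, trials, **MT_FAST)
        assert np.max(np.abs(em.map.values)) < 0.05

    def test_uniform_power_ratio_saturates(self, rng):
        a = rng.standard_normal((100, 1001)) * np.sqrt(10.0)
        b = rng.standard_normal((100, 1001))
        em = effect_size_map(a, b, **MT_FAST)
        # a tenfold power ratio dominates everywhere (d -> +1)
        assert np.min(em.map.values) > 0.8
        assert np.mean(em.map.values) > 0.97

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="time grid"):
            effect_size_map(rng.standard_normal((10, 500)),
                            rng.standard_normal((10, 600)), **MT_FAST)

    def test_sign_convention_a_greater_positive(self, rng):
        a = 2.0 * rng.standard_normal((100, 1001))
        b = rng.standard_normal((100, 1001))
        em = effect_size_map(a, b, **MT_FAST)
        assert em.map.values.mean() > 0.5


class TestBandDepthProfile:
    def _map(self, values):
        t = np.linspace(-0.4, 0.4, values.shape[1])
        f = np.arange(1.0, 1.0 + values.shape[0])
        return TimeFrequencyMap(time=t, freq=f, values=values, kind="delta")

    def test_constant_map(self):
        m = self._map(np.full((30, 5), 0.4))
        depths, t, prof = band_depth_profile([m], (4, 8))
        assert np.allclose(prof, 0.4)

    def test_two_row_mean(self):
        vals = np.zeros((30, 4))
        vals[3] = 0.2  # 4 Hz row
        vals[4] = 0.6  # 5 Hz row
        m = self._map(vals)
        _, _, prof = band_depth_profile([m], (4, 5))
        assert np.allclose(prof, 0.4)

    def test_band_outside_grid_rejected(self):
        m = self._map(np.zeros((10, 4)))  # grid 1-10 Hz
        with pytest.raises(ValueError, match="no bins"):
            band_depth_profile([m], (50, 80))

    def test_depth_ordering(self):
        m1 = self._map(np.full((30, 3), 0.1))
        m2 = self._map(np.full((30, 3), 0.9))
        depths, _, prof = band_depth_profile([m2, m1], (4, 8),
                                             depths_um=[800.0, 100.0])
        assert list(depths) == [100.0, 800.0]
        assert np.allclose(prof[0], 0.1) and np.allclose(prof[1], 0.9)


def test_tfm_validation():
    with pytest.raises(ValueError, match="increasing"):
        TimeFrequencyMap(time=[0.2, 0.1], freq=[1.0], values=np.zeros((1, 2)),
                         kind="power")
    with pytest.raises(ValueError, match="shape"):
        TimeFrequencyMap(time=[0.1], freq=[1.0], values=np.zeros((2, 2)),
                         kind="power")


def test_tfm_hdf5_roundtrip(tmp_path, rng):
    m = TimeFrequencyMap(time=np.linspace(-0.4, 0.4, 10), freq=np.arange(1.0, 6.0),
                         values=rng.random((5, 10)), kind="power",
                         params={"win_s": 0.25})
    m.to_hdf5(tmp_path / "m.h5")
    back = TimeFrequencyMap.from_hdf5(tmp_path / "m.h5")
    assert np.array_equal(back.values, m.values)
    assert back.kind == "power"
    assert back.params["win_s"] == 0.25
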