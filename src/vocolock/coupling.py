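"""Inter-areal LFP-LFP coherence between frontal-cortex depths and striatum.

Coherency is the trial-averaged cross-spectral density of two
simultaneously recorded signals, normalized by their auto-spectra; its
magnitude ("coherence") lies in [0, 1] and is sensitive to consistent
phase relationships across trials.  Unlike the locked-spectral analysis,
no randomization averaging is used here: coherograms are computed on the
per-call epochs themselves, with the same multitaper parameters as the
spectrograms (250-ms windows, TW=2, K=3).

Significance is descriptive: coherence values exceeding the 95th
percentile of all values computed for a condition (pooled over all depth
maps) are flagged.  No bias correction for trial count is applied; trial
counts are recorded in the map parameters and must accompany any
comparison.
"""

from __future__ import annotations

import warnings

import numpy as np

from .spectral import TimeFrequencyMap, _mt_params, _windowed

__all__ = [
    "coherogram",
    "average_over_cn",
    "significance_mask",
    "band_coherence_profile",
]


def coherogram(
    epochs_a: np.ndarray,
    epochs_b: np.ndarray,
    fs: float = 1000.0,
    win_s: float = 0.25,
    step_s: float = 0.0005,
    TW: float = 2,
    K: int = 3,
    fmin: float = 1.0,
    fmax: float = 90.0,
    nfft: int | None = None,
    time_offset_s: float = 0.0,
) -> TimeFrequencyMap:
    """Multitaper coherence between two aligned epoch sets.

    ``epochs_a`` and ``epochs_b`` are (n_trials, n_time) arrays of
    simultaneously recorded, trial-aligned signals.  Per window and
    frequency, C = |<S_ab>| / sqrt(<S_aa><S_bb>) with the expectation taken
    over trials and tapers.  Requires at least two trials (with one trial
    the estimate is trivially 1).
    """
    a = np.asarray(epochs_a, dtype=float)
    b = np.asarray(epochs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("epoch sets must share (n_trials, n_time) shape")
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("coherence requires >= 2 aligned trials")
    win, hop, nfft, tapers = _mt_params(fs, win_s, step_s, TW, K, nfft)
    wa = _windowed(a, win, hop)
    wb = _windowed(b, win, hop)
    sab = saa = sbb = None
    for taper in tapers:  # accumulate cross/auto spectra over tapers and trials
        fa = np.fft.rfft(wa * taper, n=nfft, axis=-1)
        fb = np.fft.rfft(wb * taper, n=nfft, axis=-1)
        xab = (fa * np.conj(fb)).sum(axis=0)
        xaa = (fa.real**2 + fa.imag**2).sum(axis=0)
        xbb = (fb.real**2 + fb.imag**2).sum(axis=0)
        sab = xab if sab is None else sab + xab
        saa = xaa if saa is None else saa + xaa
        sbb = xbb if sbb is None else sbb + xbb
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sab) / np.sqrt(saa * sbb)
    coh = np.nan_to_num(np.clip(coh, 0.0, 1.0))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sel = (freqs >= fmin) & (freqs <= fmax)
    times = time_offset_s + (np.arange(coh.shape[0]) * hop + win / 2) / fs
    return TimeFrequencyMap(
        time=times,
        freq=freqs[sel],
        values=coh[:, sel].T,
        kind="coherence",
        params={"win_s": win_s, "step_s": step_s, "TW": TW, "K": K, "fs": fs,
                "n_trials": a.shape[0]},
    )


def average_over_cn(coherograms) -> TimeFrequencyMap:
    """Element-wise mean of the coherograms of one FAF depth over CN channels."""
    maps = list(coherograms)
    if not maps:
        raise ValueError("no coherograms to average")
    ref = maps[0]
    for m in maps[1:]:
        if (
            m.time.shape != ref.time.shape
            or m.freq.shape != ref.freq.shape
            or not (np.allclose(m.time, ref.time) and np.allclose(m.freq, ref.freq))
        ):
            raise ValueError("coherograms must share grids")
    values = np.mean([m.values for m in maps], axis=0)
    params = dict(ref.params)
    params["n_cn_averaged"] = len(maps)
    return TimeFrequencyMap(
        time=ref.time, freq=ref.freq, values=values, kind="coherence", params=params
    )


def significance_mask(maps, pct: float = 95.0):
    """Percentile mask over all coherence values of one condition.

    The threshold is the ``pct`` percentile over every bin of every map in
    ``maps`` (pooled across depths); each map's mask flags bins strictly
    exceeding it.  Constant maps yield empty masks with a warning.
    Returns ``(masks, threshold)``.
    """
    maps = list(maps)
    pooled = np.concatenate([np.ravel(m.values) for m in maps])
    if pooled.size == 0:
        raise ValueError("no coherence values pooled")
    threshold = float(np.percentile(pooled, pct))
    masks = [m.values > threshold for m in maps]
    if not any(mask.any() for mask in masks):
        warnings.warn("no bin exceeds the percentile threshold (constant maps?)",
                      stacklevel=2)
    return masks, threshold


def band_coherence_profile(maps, band, depths_um=None):
    """Band-averaged coherence per FAF depth and time bin.

    Thin wrapper over :func:`vocolock.spectral.band_depth_profile` for
    coherence maps; returns ``(depths, time, matrix)``.
    """
    from .spectral import band_depth_profile

    return band_depth_profile(maps, band, depths_um=depths_um)
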