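"""Spike-LFP phase locking via bootstrapped circular statistics.

For each LFP band the epochs are zero-phase band-pass filtered and Hilbert
transformed; the instantaneous phase uses the cosine convention (peak = 0,
trough = pi).  The phase at which each spike occurred is pooled over trials
— only the pre-vocalization window [-0.5, 0) s counts — and compared with a
random-phase control pool drawn at time points not related to spiking
(samples within +/-1 ms of a spike are excluded).

Both pools are bootstrapped: n_boot times (default 10,000), m angles
(default 100) are drawn from each pool and summarized by vector strength
(VS, the resultant length of the unit phasors) and the angular mean.  dVS
is the difference of the bootstrap-mean VS (spike minus random); positive
dVS indicates spiking locked to the LFP phase.  Significance comes from a
two-sided Wilcoxon rank-sum test between the two VS samples, Bonferroni
corrected for the number of (channel x band) tests; Cliff's Delta between
the VS samples gives the effect size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import ranksums

from .bands import BANDS, get_band
from .spectral import cliffs_delta

__all__ = [
    "instantaneous_phase",
    "collect_spike_phases",
    "collect_random_phases",
    "vector_strength",
    "circular_mean",
    "bootstrap_phase_locking",
    "phase_locking_by_band",
    "PhaseLockingResult",
]


def vector_strength(angles) -> float:
    """Resultant length of unit phasors: 1 = perfect locking, 0 = uniform."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("vector strength of an empty angle set is undefined")
    return float(np.abs(np.exp(1j * angles).mean()))


def circular_mean(angles) -> float:
    """Angular mean (argument of the mean unit phasor), in (-pi, pi]."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circular mean of an empty angle set is undefined")
    return float(np.angle(np.exp(1j * angles).mean()))


def instantaneous_phase(
    epochs: np.ndarray, fs: float, band, order: int = 2
) -> np.ndarray:
    """Per-sample phase of the band-limited analytic signal.

    ``epochs`` is any array with time on the last axis.  The band-pass is
    zero-phase (order-2 Butterworth forward-backward).  A cosine at the band
    center yields phase 0 at its peaks and a phase ramp of 2*pi*f rad/s.
    All-zero input has no defined phase: flagged with a warning, NaN output.
    """
    b = get_band(band)
    x = np.asarray(epochs, dtype=float)
    if b.high_hz >= fs / 2:
        raise ValueError("band upper edge must stay below Nyquist")
    if not np.any(x):
        warnings.warn("all-zero signal: phase undefined", stacklevel=2)
        return np.full_like(x, np.nan)
    sos = sps.butter(order, [b.low_hz, b.high_hz], btype="bandpass", fs=fs,
                     output="sos")
    filt = sps.sosfiltfilt(sos, x, axis=-1)
    return np.angle(sps.hilbert(filt, axis=-1))


def collect_spike_phases(
    spike_times_s: np.ndarray,
    event_onsets_s: np.ndarray,
    phase: np.ndarray,
    time: np.ndarray,
    window: tuple[float, float] = (-0.5, 0.0),
) -> np.ndarray:
    """Band phase at each spike inside the pre-onset window of any trial.

    ``phase`` is (n_trials, n_time) aligned to ``time`` (seconds relative
    to onset); spikes are on the recording timeline and are mapped into
    each trial via its onset.  The angle is the phase at the nearest
    sample.  An empty pool is returned (not an error) when no spike falls
    in the window.
    """
    spikes = np.asarray(spike_times_s, dtype=float)
    onsets = np.asarray(event_onsets_s, dtype=float)
    time = np.asarray(time, dtype=float)
    fs = 1.0 / np.mean(np.diff(time))
    angles = []
    for ti, onset in enumerate(onsets):
        rel = spikes - onset
        sel = (rel >= window[0]) & (rel < window[1])
        if not sel.any():
            continue
        idx = np.clip(np.round((rel[sel] - time[0]) * fs).astype(int), 0,
                      time.size - 1)
        angles.append(phase[ti, idx])
    if not angles:
        warnings.warn("no spikes in the analysis window", stacklevel=2)
        return np.empty(0)
    return np.concatenate(angles)


def collect_random_phases(
    phase: np.ndarray,
    time: np.ndarray,
    n: int,
    spike_times_s: np.ndarray,
    event_onsets_s: np.ndarray,
    rng=None,
    window: tuple[float, float] = (-0.5, 0.0),
    exclusion_ms: float = 1.0,
) -> np.ndarray:
    """Random-phase control pool: phases at non-spike time points.

    Draws ``n`` (trial, sample) positions uniformly from the window,
    excluding samples within ``exclusion_ms`` of any spike of that trial.
    Errors when the window is fully occupied by exclusions or n == 0.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    spikes = np.asarray(spike_times_s, dtype=float)
    onsets = np.asarray(event_onsets_s, dtype=float)
    time = np.asarray(time, dtype=float)
    fs = 1.0 / np.mean(np.diff(time))
    in_win = (time >= window[0]) & (time < window[1])
    excl = exclusion_ms * 1e-3
    allowed_pairs = []
    for ti, onset in enumerate(onsets):
        rel_spikes = spikes - onset
        ok = in_win.copy()
        near = rel_spikes[(rel_spikes > window[0] - excl) & (rel_spikes < window[1] + excl)]
        for s in near:
            ok &= np.abs(time - s) > excl
        cols = np.flatnonzero(ok)
        allowed_pairs.append(np.column_stack([np.full(cols.size, ti), cols]))
    allowed = np.concatenate(allowed_pairs) if allowed_pairs else np.empty((0, 2), int)
    if allowed.shape[0] == 0:
        raise ValueError("window fully occupied by spike exclusion zones")
    pick = rng.integers(0, allowed.shape[0], size=n)
    return phase[allowed[pick, 0], allowed[pick, 1]]


@dataclass
class PhaseLockingResult:
    """Bootstrap phase-locking summary for one (channel, band)."""

    band: str
    vs_spike: np.ndarray  # n_boot vector strengths, spike-phase pool
    vs_random: np.ndarray  # n_boot vector strengths, random-phase pool
    angular_means: np.ndarray  # n_boot circular means of the spike draws
    dvs: float
    p_value: float  # rank-sum p, Bonferroni-corrected, capped at 1
    p_raw: float
    effect_size: float  # Cliff's Delta between the VS samples
    n_boot: int
    m: int
    n_comparisons: int
    rng_seed: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.001

    @property
    def preferred_phase(self) -> float:
        """Circular mean of the bootstrap angular means (rad)."""
        return circular_mean(self.angular_means)


def _bootstrap_draws(pool: np.ndarray, n_boot: int, m: int, rng) -> np.ndarray:
    """(n_boot, m) draws; without replacement within a draw when pool >= m."""
    pool = np.asarray(pool, dtype=float)
    if pool.size >= m:
        keys = rng.random((n_boot, pool.size))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    else:
        warnings.warn(
            f"pool of {pool.size} angles < m={m}; sampling with replacement",
            stacklevel=3,
        )
        idx = rng.integers(0, pool.size, size=(n_boot, m))
    return pool[idx]


def bootstrap_phase_locking(
    spike_pool: np.ndarray,
    random_pool: np.ndarray,
    n_boot: int = 10_000,
    m: int = 100,
    rng=None,
    n_comparisons: int = 1,
    band: str = "",
) -> PhaseLockingResult:
    """Bootstrap VS comparison between spike-phase and random-phase pools.

    Per iteration, m angles are drawn from each pool; VS is computed for
    both and the angular mean for the spike draw.  dVS is the difference of
    bootstrap-mean VS; the rank-sum p-value on the two VS samples is
    multiplied by ``n_comparisons`` (Bonferroni) and capped at 1.
    """
    spike_pool = np.asarray(spike_pool, dtype=float)
    random_pool = np.asarray(random_pool, dtype=float)
    if spike_pool.size == 0 or random_pool.size == 0:
        raise ValueError("phase pools must be non-empty")
    if n_boot <= 0 or m <= 0:
        raise ValueError("n_boot and m must be positive")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    draws_s = np.exp(1j * _bootstrap_draws(spike_pool, n_boot, m, rng))
    draws_r = np.exp(1j * _bootstrap_draws(random_pool, n_boot, m, rng))
    mean_s = draws_s.mean(axis=1)
    vs_spike = np.abs(mean_s)
    ang_means = np.angle(mean_s)
    vs_random = np.abs(draws_r.mean(axis=1))
    stat = ranksums(vs_spike, vs_random)
    p_corr = min(1.0, stat.pvalue * n_comparisons)
    return PhaseLockingResult(
        band=band,
        vs_spike=vs_spike,
        vs_random=vs_random,
        angular_means=ang_means,
        dvs=float(vs_spike.mean() - vs_random.mean()),
        p_value=float(p_corr),
        p_raw=float(stat.pvalue),
        effect_size=cliffs_delta(vs_spike, vs_random),
        n_boot=n_boot,
        m=m,
        n_comparisons=n_comparisons,
        rng_seed=int(seed) if seed is not None else None,
    )


def phase_locking_by_band(
    epochs: np.ndarray,
    time: np.ndarray,
    fs: float,
    spike_times_s: np.ndarray,
    event_onsets_s: np.ndarray,
    bands=None,
    n_boot: int = 10_000,
    m: int = 100,
    rng=None,
    window: tuple[float, float] = (-0.5, 0.0),
    n_comparisons: int | None = None,
) -> dict[str, PhaseLockingResult]:
    """Run the full per-band phase-locking analysis for one channel.

    ``epochs`` is (n_trials, n_time) LFP for the channel; the Bonferroni
    family defaults to the number of bands tested here (scale it by the
    number of channels when looping externally).
    """
    bands = list(BANDS.values()) if bands is None else [get_band(b) for b in bands]
    if n_comparisons is None:
        n_comparisons = len(bands)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    results = {}
    for band in bands:
        phase = instantaneous_phase(epochs, fs, band)
        spool = collect_spike_phases(spike_times_s, event_onsets_s, phase, time, window)
        if spool.size == 0:
            continue
        rpool = collect_random_phases(
            phase, time, max(spool.size, m), spike_times_s, event_onsets_s, rng,
            window,
        )
        results[band.name] = bootstrap_phase_locking(
            spool, rpool, n_boot=n_boot, m=m, rng=rng,
            n_comparisons=n_comparisons, band=band.name,
        )
    return results
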