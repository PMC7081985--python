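# Methods

This note documents the models, estimators and numerical choices behind
`vocolock`, and what the synthetic-data tests do and do not establish about
real recordings.

## Call processing

Calls are classified by the frequency of the maximum of the *de-noised*
magnitude spectrum: |FFT(call)| − |FFT(noise)| floored at zero, with a
duration-matched noise snippet taken immediately before the call onset
(1-ms guard).  Ties break toward the lower frequency; an all-zero difference
has no defined peak (NaN).  A peak above 50 kHz is an echolocation pulse, at
or below 50 kHz a communication call (the boundary is assigned to
communication and is configurable).  Communication calls are LHF when the
power maximum above 50 kHz is at least half the maximum below (inclusive
boundary), else LF.  The global de-noised-FFT peak is used, without trying
to distinguish fundamentals from harmonics.

The envelope detector (rectified signal smoothed with a 0.1-ms moving
average; threshold median + 5·MAD/0.6745; merge gaps < 1 ms; discard
segments < 0.2 ms) is deliberately simple — real datasets of this kind were
annotated manually, and the detector exists so the pipeline runs end to end.
Call spectrograms use 0.8-ms Hamming frames, 0.05-ms shift, 2,048-point FFT.

Isolation: a call is analysis-grade when no other call intrudes on the
500 ms before onset or after offset (and both margins fit inside the
recording).  Calls with a clean pre-window but a contaminated post-window
form the decoder's generalization control set.

## Signal conditioning

All filters are order-2 Butterworth applied forward–backward
(`sosfiltfilt`).  Zero-phase filtering is a deliberate choice the downstream
phase analyses depend on; a causal filter would bias every phase estimate.
The LFP chain: band-pass 1–90 Hz → line-noise removal → polyphase
anti-aliased decimation to 1 kHz (integer factors only) → z-scoring over the
whole recording (not per epoch), across channels for the FAF so laminar
amplitude gradients survive, per channel for the CN.  Line noise is removed
by least-squares regression of sine/cosine pairs at the line frequency and
its first harmonic in 1-s windows stepped by 0.5 s, recombined by
Hann-weighted overlap-add; on clean data the regression removes only the
~4/1000 of variance any 4-regressor fit would.

Spikes are negative-going crossings of 5 Gaussian-consistent MADs
(MAD/0.6745) in the 300–3,000 Hz band, timed at the trough, with a 1-ms
lockout.  This is threshold multi-unit activity; template-matching spike
sorting is intentionally out of scope, and externally sorted spike times can
be supplied as CSV.  PSTHs use 3-ms half-open bins, spikes per trial per
bin.  Best frequency is the stimulus maximizing the summed |analytic
signal| of the trial-averaged response after onset, ties to the lower
frequency.

## Randomization trials and Cliff's Delta maps

A randomization trial is the average of k (default 100) epochs drawn
uniformly without replacement from one condition (with replacement, with a
warning, when the pool is smaller than k); n_rand (default 10,000) trials
are drawn independently.  Averaging suppresses components not time-locked
to the call.  Multitaper spectrograms use 250-ms windows, time-bandwidth
TW = 2, K = 3 Slepian tapers, FFTs zero-padded to ≥ 1-Hz resolution
(nfft = 1024 at 1 kHz).  The nominal 0.5-ms step is below one sample at
1 kHz; the hop floors at one sample, and the desk-scale analyses here use a
2–5-ms hop (a pure problem-size choice — the estimator is unchanged).  The
FFT stage runs in single precision, which is immaterial for a rank-based
distributional statistic and ~3× faster.  Power scales exactly with
amplitude² (verified at amplitudes 1, 2, 4).

Effect maps compute Cliff's Delta per time-frequency bin between the two
conditions' across-trial distributions of log₁₀ power (d is invariant to
any joint monotone transform, so the log only fixes the reported scale),
via the rank identity d = 2·AUC − 1 with average ranks for ties — verified
exactly against brute-force pairwise enumeration.  The sign convention is
positive = more power during echolocation.

**Null calibration scales with n/k.**  Because every randomization trial
concentrates near its condition's pool mean, the background |d| between two
same-distribution conditions does not vanish: per bin it behaves like a
ratio of the pool-mean sampling noise (∝ 1/√n) to the trial spread
(∝ √((n−k)/(k(n−1)))), i.e. grows like √(k/n).  Measured on class-blind
sessions (k = 50): with 100 epochs/class ~38 % of bins exceed the medium
border; with 300, ~1 %; with 1,000, none, and the 95th percentile of |d|
is ≈ 0.12.  The synthetic suites therefore use pools of 400 epochs/class
for recovery analyses and 1,000 for null calibration — chosen once from
this scaling law, matching or exceeding the n/k ≈ 6 of a realistic
session.  The practical reading for real data: with pools only a few times
k, background |d| of 0.2–0.3 is expected from sampling noise alone, and
only effects clearing the medium border in a localized band/window are
interpretable.

Detection floor: with the default 1/f background (σ = 1), a Gaussian burst
of peak amplitude (gain) g confined to a band adds roughly
0.18·g² to that band's epoch power against a pink-noise band power of
0.08–0.11; g ≳ 0.7 reliably clears the medium border at n/k = 8, and the
generator defaults (g = 1.2–1.5) sit well above this floor, saturating
d near ±1.

## Decoding

Features are the time series of band-averaged log₁₀ power (log of the
band-mean, not mean of logs) inside the pre- ([−0.5, 0) s) or post-window,
one row per randomization trial.  The classifier is sklearn's `SVC` with
rbf kernel, C = 1, **kernel scale 1** (gamma = 1), no standardization, no
hyperparameter search, trained once.  Kernel scale 1 is the
classifier-toolbox default of the original analysis and is load-bearing:
these features form two tight clusters, and with a scale of √d the kernel
is nearly global, so a label-shuffled model degenerates to the per-cluster
majority of the permuted labels and its accuracy becomes bimodal (anywhere
from ~10 % to ~60 %).  With scale 1 the kernel is local, shuffled-label
accuracy concentrates near 50 %, and the informative accuracy is unchanged;
the scale is exposed as a parameter.  Train, held-out and contaminated sets
are disjoint at the randomization-trial level (the original study's
convention);
note all three descend from the same call pool, so "held-out" measures
generalization across trial resampling, not across sessions.

## Coherence

Coherograms use the same multitaper parameters on per-call epochs — no
randomization averaging — averaging cross- and auto-spectra over trials and
tapers; at least two trials are required.  No small-sample bias correction
is applied (matching the original procedure); trial counts are stored in
the map parameters, and with ~60 trials × 3 tapers the independent-noise
bias stays below 0.1–0.2.  Significance is descriptive: values strictly
above the 95th percentile of all bins of all depth maps of one condition.
The pool is per condition; per-pair pooling is available via the functions'
inputs.  Coherence is exactly 1 for identical inputs and invariant to
positive rescaling of either signal.

## Spike–phase locking

Band phases come from order-2 zero-phase band-pass plus Hilbert transform,
cosine convention (peak = 0, trough = π).  Spike angles are collected only
in the pre-vocalization window [−0.5, 0) s, at the nearest sample; the
random-phase control draws time points uniformly from the same windows
excluding ±1 ms around any spike.  Both pools are bootstrapped: n_boot
draws of m = 100 angles (without replacement within a draw when the pool
allows), VS and angular mean per draw; dVS is the difference of
bootstrap-mean VS; p comes from a two-sided rank-sum between the two VS
samples, multiplied by the number of (channel × band) tests and capped at
1; Cliff's Delta between the VS samples is the effect size.  VS closed
forms are verified in the tests: VS({0, π/2}) = √2⁄2, E[VS] of 100 uniform
angles ≈ √(π/400) ≈ 0.0886, and a von Mises(κ = 5) pool recovers
I₁(5)/I₀(5) ≈ 0.893.

**The rank-sum on bootstrap distributions is anti-conservative.**  The
n_boot replicates are resamples of two fixed finite pools, so the test
effectively asks whether the two *pools* differ at a resolution that
sharpens with n_boot.  Under a true null (κ = 0), measured false-positive
rates at corrected p < 0.001 are near 1 when the pools are smaller than
n_boot and fall to zero once pools exceed ~5× n_boot.  The suites therefore
match n_boot to pool size (e.g. n_boot = 1,000 against ~5,000-spike pools),
and the same discipline is recommended on real data.  Weak but genuine
high-gamma locking also appears in full-session runs because inserted spike
waveforms bleed into the 50–80 Hz LFP band — the synthetic analogue of a
well-known artifact of spike-contaminated LFPs.

## Synthetic sessions

The generator is the testbed, not a biophysical model.  It emulates:
1/f^α background (spectral shaping of white noise, α = 1 by default, slope
recovered within ±0.2 over 2–80 Hz); Gaussian-windowed band-limited bursts
time-locked to call onsets with uniformly random per-trial phase (so only
power, not waveform, survives randomization averaging), assigned by class,
region and depth range; a shared narrowband component across regions with a
class-dependent window and a fixed FAF→CN lag (10 ms default) carrying the
coherence structure; a deterministic damped post-onset deflection in FAF
channels ≥ 400 μm (depth-scaled) and, weaker, in the CN; and spiking as an
inhomogeneous Poisson process (exact thinning) with von Mises intensity
exp(κ·cos(φ − φ₀))/I₀(κ) on a configurable band phase, elevated for 100 ms
after each call, inserted into the wideband trace as ~0.5-ms biphasic
waveforms of amplitude ≈ 12 detection-MADs.  Defaults encode the study
conditions: pre-call gamma biased to echolocation (CN and deep FAF),
pre-call beta to communication, theta coherence pre-onset for communication
versus > 250 ms post-onset for echolocation, θ-locked spiking with κ = 2 at
phase π.  Audio embeds cosine-tapered tones/sweeps (72-kHz down-FM pulses,
14-kHz communication calls, LHF variant with a 60-kHz component) in
low-level noise at 250 kHz.  Everything is driven by
`numpy.random.default_rng` seeds spawned from one `SeedSequence`; identical
configs are bit-identical, and HDF5 artifacts are written without
timestamps so reruns hash identically.

What passing tests do **not** show about real data: the generator's classes
differ by clean stationary band bursts, its background is Gaussian and
stationary, its spikes are Poisson, and its calls are two fixed templates —
so the suites validate the estimators and their calibration, not the
biological claims.  Full-scale numbers from real recordings (e.g. decoding accuracy of a
specific channel/band on real recordings) are not reproducible from text
alone and are not targets here.

## Problem sizes and other defaults

Library defaults are the study values (n_rand = 10,000, k = 100,
n_boot = 10,000, m = 100, 0.5-ms spectrogram step).  The analysis scripts
and tests run scaled versions chosen once: 400–1,000 epochs/class pools,
n_rand = 1,000–2,000, k = 50, 2–5-ms hop, nfft = 512, n_boot matched to
phase-pool size; these keep every suite within a few minutes on one CPU
while preserving the statistics being tested (d and VS are
distribution-level quantities, stable under these scalings — the
equivalences are exercised by the oracle tests).  The reported median call
duration of ~0.33 ms circulating for this species' isolated calls is treated
as a likely typographical artifact; generator templates default to 1 ms (echolocation) and 5 ms
(communication) and the value is configurable, not hard-coded.
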