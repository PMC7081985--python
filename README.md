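# vocolock

Vocalization-locked analysis of fronto-striatal field potentials in bats.

Echolocating bats emit two kinds of calls — short (<2 ms), downward
frequency-modulated echolocation pulses peaking above 50 kHz, and longer
communication calls with most energy below 50 kHz.  `vocolock` re-implements,
as a tested and reusable Python pipeline, the analyses that link local field
potentials (LFPs) recorded simultaneously in the frontal auditory field (FAF,
a 16-channel laminar probe, depths 50–800 μm) and the caudate nucleus (CN,
dorsal striatum) to the bat's vocal output:

1. **Call processing** — envelope detection, de-noised-FFT peak frequency
   (|FFT(call)| − |FFT(noise)| floored at 0), the 50-kHz class rule, the
   LF/LHF split (high-band maximum ≥ half the low-band maximum → LHF), and
   selection of temporally isolated calls (≥ 500 ms of silence on both sides).
2. **Signal conditioning** — 1–90 Hz zero-phase Butterworth band-pass,
   sliding-window line-noise regression, 20 kHz → 1 kHz decimation, z-scoring
   (across channels for the FAF, per channel for the CN), ±500 ms epochs
   around call onset; multi-unit spike detection at 5 median absolute
   deviations in the 300–3,000 Hz band; 3-ms PSTHs; pure-tone best-frequency
   tuning via Hilbert energy.
3. **Locked spectral contrast** — *randomization trials* (averages of k = 100
   randomly chosen epochs of one condition, n = 10,000 trials) isolate
   call-locked signal components; multitaper spectrograms (250-ms windows,
   TW = 2, K = 3 Slepian tapers) of each trial feed a per-bin Cliff's Delta

   d = (#{aᵢ > bⱼ} − #{aᵢ < bⱼ}) / (nₐ·n_b)  ∈ [−1, 1]

   between the two conditions' log-power distributions, with borders
   0.147 / 0.333 / 0.474 for small / medium / large effects.
4. **Decoding** — per band, the time series of band-averaged log power before
   (or after) the call is fed to a binary rbf-kernel SVM (trained once, no
   standardization), with 10-fold cross-validation, a label-shuffle control,
   and generalization to trials whose post-window was contaminated by other
   sounds.
5. **Coupling** — multitaper coherence C(t,f) = |⟨S_ab⟩| / √(⟨S_aa⟩⟨S_bb⟩)
   between each FAF depth and the CN on per-call epochs, masked at the 95th
   percentile of all values per condition, plus band/depth timing profiles.
6. **Spike–phase locking** — per band, Hilbert phases at spike times
   (pre-vocalization window only) versus a random-time-point control;
   bootstrap vector-strength (VS) distributions (10,000 draws of 100 angles),
   dVS = mean VS_spike − mean VS_random, Bonferroni-corrected rank-sum tests
   and Cliff's Delta effect sizes.

A first-class synthetic-session generator (`vocolock.synth`) emulates the
recording structure — 250-kHz audio with both call classes, 1/f LFP
background, class/region/depth-dependent band bursts, class-dependent
inter-areal theta timing, evoked deflections in deep FAF channels, and
von Mises phase-locked spiking — and records the ground truth needed for
parameter-recovery tests.

## Worked example

The numbered scripts under `analysis/` run the whole study on one synthetic
session (4 FAF depths, 2 CN channels, 40 calls/class) and write their tables
to `results/`:

```bash
python analysis/01_simulate_session.py      # audio + wideband traces + spikes
python analysis/02_detect_and_classify_calls.py
python analysis/03_condition_signals.py
python analysis/04_effect_size_maps.py
python analysis/05_coherence.py
python analysis/06_spike_phase_locking.py
python analysis/07_decode_call_type.py
```

Output of a full run (seed 2026):

```
detected 80/80 calls; class recovery 100.0%
  median peak frequency, communication: 14.0 kHz
  median peak frequency, echolocation: 72.0 kHz
FAF 50 um: strongest pre-call effect in high_beta (d = -0.83)
CN 200 um: strongest pre-call effect in high_gamma (d = +0.95)
communication: theta coherence peaks at -0.210 s
echolocation: theta coherence peaks at +0.330 s
15/36 (channel, band) pairs significant (corrected p < 0.001)
strongest locking: channel 3 in theta (dVS = 0.602, preferred phase -3.04 rad)
high_gamma: accuracy  91.2%  cv error 0.092  shuffled  46.0%
```

Reading the numbers: both call classes are recovered perfectly from their
spectra (72 vs 14 kHz); the striatal channel shows a large pre-call
high-gamma effect favoring echolocation and the FAF a beta effect favoring
communication — exactly the structure the generator injected; fronto-striatal
theta coherence peaks before communication calls but ~300 ms after
echolocation pulses; spiking locks to theta (preferred phase ≈ π, the
generator's target) and nowhere strongly else; and pre-call high-gamma power
decodes the upcoming call type at 91% while permuting the training labels
drops accuracy to chance.

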