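# Methods

This note describes what `spkrecon` computes, the assumptions behind each
stage, and the numerical and design choices that matter when interpreting its
output.

## Problem

Extracellular electrophysiology needs ≥ 10 kHz sampling to resolve action
potentials (spikes, ~1 ms biphasic transients of tens to hundreds of μV), but
bandwidth- or power-constrained acquisition systems often store only a
low-pass-filtered, heavily subsampled signal. `spkrecon` learns to
reconstruct the high-frequency (spike-band) signal from that degraded input:
given a wide-band recording sampled at `fs` (default 25 kHz), the low band
below 200 Hz subsampled by a factor `M` is the network input, and the
high band above 200 Hz at full rate is the supervised target. Because the
low band retains weak, temporally aligned signatures of spiking (residual
spike energy below the cutoff), a learned mapping can recover spike timing
and approximate waveforms that threshold detection on the input alone cannot.

## Preprocessing

Each electrode trace `x` is split into complementary bands
(`dsp.butterworth_split`):

- **zero_phase** (default): order-4 Butterworth low-pass at 200 Hz applied
  forward-backward (`scipy.signal.sosfiltfilt`), high band = `x − lpf`.
  Zero-phase filtering squares the magnitude response, so the gain at the
  cutoff is exactly 1/2 and no group delay is introduced; the split is
  exactly complementary by construction (`lpf + hpf = x` to rounding).
  Forward-backward filtering has edge transients; identities are only
  guaranteed ≥ `3 · order · fs / cutoff` samples (1500 at the defaults)
  from each end.
- **ideal_brickwall**: real-FFT masking, bins with frequency ≤ cutoff go to
  the low band. Exactly complementary everywhere; useful as an oracle.

The low band is decimated by stride `M` (`x[::M]`; the 200 Hz cutoff is far
below the post-decimation Nyquist for all supported `M`, so no further
anti-aliasing is needed) and restored to the original grid by Fourier
interpolation of factor `L = M` (`scipy.signal.resample`). For a
bandlimited signal, interpolation by `L` followed by stride-`L` decimation is
the identity to ~1e-15, which pins down the sample-grid convention.

Both bands are divided by a per-electrode scale: the maximum absolute value
of the high band over spike-free samples. Spike-free means at least 2 ms from
any −5 SD crossing, where SD is the robust noise estimate
`median(|x|)/0.6745` (the MAD estimator, insensitive to the spikes
themselves). The scale is stored in `NormalizedPair` so reconstructions can
be mapped back to physical μV.

## Network

`SpkRecon` maps an interpolated low-band window of `T = 128` samples to the
high-band window of the same length (no upsampling layer — resolution is
restored before the network):

- a length-3 1D convolution lifts 1 → `C` channels (shallow feature `F_SF`);
- `n_rstb` residual blocks, each `n_stl` shifted-window transformer layers
  followed by a convolution and a residual connection, produce the deep
  feature `F_DF`;
- a final convolution projects `F_SF + F_DF` back to one channel.

Each transformer layer is pre-norm: LayerNorm → windowed multi-head
self-attention (window `w = 8`) → residual, then LayerNorm → 2-layer MLP
(hidden ratio 2, GELU) → residual. Attention logits are
`QKᵀ/√d + B` with a learned relative-position bias table of `2w − 1` entries
per head. Alternate layers cyclically shift the sequence by `w/2` before
windowing and add a −1e9 mask on pairs that wrap around the seam, so
information propagates across window boundaries without changing the
sequence length. The full-scale configuration is `C = 180`, 6 blocks × 6
layers, 6 heads; all tests and the demonstration study use smaller
configurations of the same code.

Three reference families are provided for comparison: a SwinIR-style network
(same trunk, fed the *decimated* window, ending in a 1D sub-pixel-shuffle
upsampler of factor `M`), an EDSR-style residual CNN with upsampler, and a
TCN of dilated causal convolutions predicting one sample ahead.

Because no deep-learning framework is a dependency, the networks run on an
in-package reverse-mode automatic-differentiation engine over NumPy float64
arrays (`spkrecon.nn`). Gradients of every primitive are verified against
finite differences in the test suite. This keeps the package pure-Python but
bounds practical model sizes; the demonstration study uses a ~58k-parameter
network.

## Training: spike-focused window selection

Spikes occupy ≪ 1% of samples, so uniformly sampled training windows are
dominated by background and a short training budget never learns the spike
mapping. Spike-focused window selection (SFWS) builds each minibatch of `B`
windows so that:

- the first `B/2` are anchored: a ground-truth spike peak `n` (a −6 SD
  event minimum on the high-band target, indexed once before training) is
  chosen uniformly, a jitter `τ` is drawn uniformly from the integers
  `(−W/2, W/2]`, and the window is `[n + τ − W/2, n + τ + W/2)`. The peak
  thus always lies inside the window, at a position uniform on
  `{0, …, W−1}`, so the network never learns a positional shortcut;
- the remaining `B/2` are uniform over electrodes and positions, preserving
  exposure to pure background.

Windows that would cross a trace boundary are redrawn. Training minimizes
mean squared error between the network output and the normalized high-band
window with Adam at a fixed learning rate; everything is deterministic under
the configured seed.

Full traces are reconstructed by sliding the `W`-sample window at a stride
(default 64), averaging overlapping predictions sample-wise; the last window
is right-aligned so output length equals input length. Averaging (rather
than center-cropping) was chosen because it is stateless, covers every
sample, and empirically suppresses window-edge artifacts.

## Evaluation

Spikes are detected as −6 SD threshold crossings of the relevant trace
(noise SD via MAD), with crossings closer than 1 ms merged and the event
minimum taken as the timestamp. Detected and ground-truth trains are matched
one-to-one within ±500 μs by an interval-scheduling sweep (process
ground-truth spikes in order; assign each the earliest still-free detection
inside its tolerance window). For a single shared tolerance this greedy rule
attains the maximum possible number of matches — verified in the tests
against exhaustive enumeration — whereas a nearest-first rule does not
(gt = {0, 6}, rec = {4, 10}, tol = 5: nearest-first pairs 4↔6 and strands
both others). Reported metrics:

- **hit rate** = TP / (TP + FN), **precision** = TP / (TP + FP);
- **mean time delay** of matched pairs, in μs;
- **waveform NRMSE**: RMSE over a −1…+2 ms window around each matched
  ground-truth peak, divided by that window's ground-truth peak-to-peak
  amplitude.

Spike-train analyses: firing-rate histograms in half-open 50 ms bins;
functional connectivity as the Pearson correlation matrix of rate histograms
(diagonal 1 by definition; entries involving a constant histogram are NaN);
spike sorting as PCA to 2 components plus seeded K-Means (k ∈ {2, 3}) with
accuracy scored as the best label permutation via optimal assignment on the
contingency table. A short-time Fourier spectrogram of the low band uses a
symmetric Hamming window of 1250 samples with 1125-sample overlap at
3125 Hz (40 ms hop); an optional `n_freq` (e.g. 616) fixes the number of
one-sided bins by setting the transform length to `2·(n_freq − 1)` and
truncating.

## Synthetic recordings

The generator (`synthio`) emulates: biphasic spike templates (negative
Gaussian lobe of given FWHM plus a smaller positive rebound, tapered to
exactly zero tails, minimum exactly at the configured amplitude); per-unit
Poisson firing with optional burst expansion (each event spawns a short
4–10 ms-ISI burst with configured probability/size) under a 2 ms absolute
refractory period; low-frequency field oscillations as fixed-amplitude
sinusoids with random phases; white (optionally 1/f-shaped) Gaussian noise;
and pairwise co-firing across electrodes via shared Poisson sources with
per-channel jitter bounded so pairwise offsets stay below the configured
window. It does **not** emulate electrode drift, bursting amplitude
adaptation, spatial waveform overlap across channels, or realistic spike
shape variability within a unit — conclusions about those phenomena cannot
be drawn from these simulations.

## Demonstration study

`pipeline.run_study` fixes the package's demonstration conditions: 8
electrodes × 120 s at 25 kHz, one unit per electrode at −120 μV (1 ms
width), 5 Hz with 15% bursts, 10 μV noise, field components of 10/6/3 μV at
2/8/30 Hz; `M = 8`; a small network (`T = 128`, `C = 16`, 2 × 2 layers, 2
heads); 800 Adam steps at batch 16, learning rate 2e-3 (scaled up from the
full-scale default 1e-4 for the much smaller network and short budget); 2
held-out electrodes evaluated on 60 s segments. An ablation arm retrains
with SFWS disabled at the identical seed and budget. Typical results:
hit rate ≈ 0.8–0.9 with precision ≈ 0.99 and NRMSE ≈ 0.12 on held-out
electrodes, while threshold detection on the input alone, and the SFWS-off
arm at this budget, recover essentially nothing.

## Known limitations

- The autodiff engine is single-threaded NumPy; full-scale configurations
  (`C = 180`, 6 × 6) train only at unrealistic wall-clock cost here.
- The matching tolerance is global; per-unit tolerances are not supported.
- Normalization assumes at least some spike-free background on every
  electrode; a trace that is all spikes (or all zeros) is rejected.
- Detection-based metrics share the −6 SD convention between ground truth
  and reconstruction; units whose reconstructed amplitude falls below that
  threshold are counted as misses even when timing information is present.
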