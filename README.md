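# spkrecon

Reconstruction of high-frequency extracellular spike signals from
low-pass-filtered, heavily subsampled recordings, with a 1D shifted-window
attention transformer trained by spike-focused window selection.

## The problem

Resolving extracellular action potentials requires sampling at ≥ 10 kHz,
but bandwidth- and power-constrained acquisition systems often store only a
low-pass-filtered signal at a fraction of that rate. The low band (< 200 Hz)
still carries weak, temporally aligned traces of spiking activity, so a
learned mapping can recover spike timing and approximate waveforms that are
invisible to threshold detection on the stored signal. `spkrecon` implements
the full chain:

1. **Preprocessing** (`spkrecon.dsp`) — zero-phase order-4 Butterworth band
   split at 200 Hz, decimation of the low band by a factor *M*, Fourier
   re-interpolation back to the original grid (*L = M*), and per-electrode
   normalization by the spike-free high-band amplitude.
2. **Model** (`spkrecon.model`) — `SpkRecon`, a 1D shifted-window attention
   transformer: a shallow convolution lifts the *T* = 128-sample window to
   *C* feature channels, residual blocks of windowed multi-head
   self-attention layers (window 8, alternating cyclic shift 4 with seam
   masking, relative position bias) produce the deep feature, and a final
   convolution maps the shallow + deep feature sum back to one channel.
   Output length always equals input length. SwinIR-style, EDSR-style, and
   TCN reference families are included. Networks run on an in-package NumPy
   autodiff engine (`spkrecon.nn`) — no deep-learning framework required.
3. **Training** (`spkrecon.training`) — spike-focused window selection
   (SFWS): half of every minibatch is anchored on a ground-truth spike peak
   with uniform jitter so the peak position is uniform over the window, the
   other half is uniform background; MSE loss, Adam.
4. **Metrics** (`spkrecon.metrics`) — −6 SD threshold detection with 1 ms
   dead time, optimal one-to-one train matching within ±500 μs, hit
   rate / precision / mean delay, and waveform NRMSE over −1…+2 ms windows.
5. **Analysis** (`spkrecon.analysis`) — rate histograms, Pearson
   functional-connectivity matrices, PCA + K-Means spike sorting with
   best-permutation accuracy, and low-band spectrograms.
6. **Synthetic recordings** (`spkrecon.synthio`) — seeded multichannel
   generator (biphasic templates, Poisson/burst firing, field oscillations,
   Gaussian noise, pairwise co-firing) used throughout the tests and the
   demonstration study.

See `docs/methods.md` for assumptions, conventions, and limitations.

## Worked example

The demonstration study (`spkrecon.pipeline`) runs the whole chain at a
desk scale: an 8-electrode, 2-minute synthetic recording at 25 kHz
(one −120 μV unit per electrode, 5 Hz with bursts, 10 μV noise, field
oscillations), preprocessing at *M* = 8, a small SpkRecon
(*T* = 128, *C* = 16, 2 blocks × 2 layers) trained for 800 steps with SFWS,
and evaluation on 2 held-out electrodes:

```python
from spkrecon.pipeline import StudyConfig, run_study

results = run_study(StudyConfig(), with_ablation=True)
for arm in ("sfws", "no_sfws"):
    r = results[arm]
    print(f"{arm:8s} hit={r['hit_rate']:.3f} precision={r['precision']:.3f} "
          f"nrmse={r['nrmse']:.3f} input_hit={r['input_hit_rate']:.3f}")
```

Output of this exact snippet (seed 1, ~7 minutes on one CPU core):

```
sfws     hit=0.934 precision=0.986 nrmse=0.120 input_hit=0.000
no_sfws  hit=0.000 precision=nan nrmse=nan input_hit=0.000
```

The trained network recovers 93% of held-out spikes at 99% precision with
waveform NRMSE 0.12, while threshold detection on the low-band input alone
recovers none, and the same training budget without spike-focused selection
learns nothing — uniformly sampled windows are almost entirely background.

The same pipeline is scriptable from the command line
(`spkrecon simulate | preprocess | train | reconstruct | evaluate |
analyze`); see `spkrecon --help`.

## Reproduction

`scripts/acceptance.py` runs the study plus the filter-bank, sorting, and
connectivity checks from scratch and writes the headline quantities as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

For seed 1 this prints (6.6 minutes on one CPU core):

```
band_split_residual: 9.68111e-14  (n=97000)
interpolation_stride_error: 1.86517e-14  (n=25000)
cutoff_gain: 0.5  (n=97000)
sorting_accuracy: 1  (n=337)
independent_pair_correlation: -0.00726689  (n=6000)
hit_rate: 0.863247  (n=746)
precision: 0.998542  (n=645)
waveform_nrmse: 0.125818  (n=746)
input_hit_rate: 0  (n=746)
hit_rate_no_sfws: 0  (n=746)
final_train_mse: 0.102978  (n=800)
```

All randomness derives from `--seed`; the study's internal seed is itself
derived from it, so these numbers differ slightly from the worked example
above, which uses the study's default seed. The full-chain property tests
live in `tests/test_acceptance.py`.
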