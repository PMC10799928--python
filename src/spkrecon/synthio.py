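"""Synthetic multichannel extracellular recordings with known ground truth.

Each channel carries sparse biphasic spike waveforms from one or more units
(Poisson event process with optional burst expansion and a 2 ms absolute
refractory period), a sum of low-frequency sinusoidal components standing in
for LFP-band activity, and additive Gaussian background noise (optionally
1/f-shaped).  Because injected spike times, unit identities and the clean
trace are all returned, every downstream stage — filtering, training,
detection, matching, sorting, connectivity — can be scored against exact
ground truth.

Defaults emulate a 25 kHz multielectrode recording of cultured neurons with
tonic firing and occasional bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_FS = 25_000.0
REFRACTORY_MS = 2.0           # absolute per-unit refractory period
BURST_ISI_MS = (4.0, 10.0)    # intra-burst inter-spike intervals


@dataclass
class TemplateParams:
    """One unit's spike waveform: negative peak amplitude (μV, < 0), width of
    the negative lobe (ms), and the positive-rebound amplitude as a fraction
    of the negative peak."""

    amplitude: float = -100.0
    width_ms: float = 1.0
    biphasic_ratio: float = 0.3

    def validate(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("template width must be positive")
        if not np.isfinite(self.amplitude) or self.amplitude >= 0:
            raise ValueError("template amplitude must be finite and negative")


@dataclass
class SynthConfig:
    n_channels: int = 4
    duration: float = 10.0
    fs: float = DEFAULT_FS
    units_per_channel: int = 1
    firing_rate: float = 5.0
    burst_prob: float = 0.2
    burst_size: int = 3
    noise_sigma: float = 10.0
    lfp_components: list[tuple[float, float]] = field(
        default_factory=lambda: [(2.0, 10.0), (8.0, 6.0), (30.0, 3.0)]
    )
    template_params: list[TemplateParams] | None = None
    correlation: np.ndarray | None = None   # pairwise co-firing probabilities
    cofire_jitter_ms: float = 5.0           # max |jitter| of shared events (exclusive)
    noise_one_over_f: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.firing_rate < 0:
            raise ValueError("firing_rate must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for f, a in self.lfp_components:
            if not (np.isfinite(f) and np.isfinite(a)):
                raise ValueError("LFP components must be finite")

    def resolved_templates(self) -> list[TemplateParams]:
        if self.template_params is not None:
            tp = list(self.template_params)
            if len(tp) != self.units_per_channel:
                raise ValueError("need one TemplateParams per unit")
            return tp
        # default family: amplitudes spread so units are separable
        return [
            TemplateParams(amplitude=-100.0 * (1.0 + 0.6 * u), width_ms=1.0 + 0.3 * u)
            for u in range(self.units_per_channel)
        ]


@dataclass
class GroundTruth:
    """spike_times[channel][unit] -> sorted sample indices of negative peaks."""

    spike_times: list[list[np.ndarray]]
    unit_ids: list[list[int]]
    clean_trace: np.ndarray
    noise_trace: np.ndarray
    lfp_trace: np.ndarray
    fs: float

    def all_times(self, channel: int) -> np.ndarray:
        per_unit = self.spike_times[channel]
        if not per_unit:
            return np.array([], dtype=int)
        return np.sort(np.concatenate(per_unit)).astype(int)

    def labeled_times(self, channel: int) -> tuple[np.ndarray, np.ndarray]:
        """(sorted sample indices, unit label per spike) for one channel."""
        times, labels = [], []
        for u, t in zip(self.unit_ids[channel], self.spike_times[channel]):
            times.append(t)
            labels.append(np.full(len(t), u))
        if not times:
            return np.array([], dtype=int), np.array([], dtype=int)
        t = np.concatenate(times)
        l = np.concatenate(labels)
        order = np.argsort(t, kind="stable")
        return t[order].astype(int), l[order].astype(int)


@dataclass
class Recording:
    signal: np.ndarray           # (n_channels, n_samples), μV
    fs: float
    channel_ids: list | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def make_templates(template_params: list[TemplateParams], fs: float) -> list[dict]:
    """Biphasic spike templates on a ~3x width support.

    Shape: a negative Gaussian lobe of the requested width followed by a
    slower positive rebound, scaled so the global minimum equals `amplitude`
    exactly.  Returns per unit a dict with 'waveform' (μV), 'peak' (sample
    index of the minimum) and 'fs'.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    out = []
    for tp in template_params:
        tp.validate()
        w_s = tp.width_ms * 1e-3
        half = max(3, int(round(1.5 * w_s * fs)))
        t = (np.arange(2 * half + 1) - half) / fs
        neg = -np.exp(-0.5 * (t / (w_s / 2.355)) ** 2)       # FWHM = width
        pos = tp.biphasic_ratio * np.exp(
            -0.5 * ((t - 0.9 * w_s) / (w_s / 1.2)) ** 2
        )
        wave = neg + pos
        wave *= tp.amplitude / wave.min()                     # min == amplitude
        # taper tails to zero so the support is finite
        taper = np.minimum(1.0, np.minimum(np.arange(len(t)), np.arange(len(t))[::-1]) / 3.0)
        wave *= taper
        wave *= tp.amplitude / wave.min()
        peak = int(np.argmin(wave))
        out.append({"waveform": wave, "peak": peak, "fs": fs})
    return out


def _unit_spike_times(
    rng: np.random.Generator, cfg: SynthConfig, n_samples: int, margin: tuple[int, int],
    event_times: np.ndarray | None = None,
) -> np.ndarray:
    """Event process -> spike sample indices with bursts and refractory period.

    If `event_times` (sample indices) is given it is used as the event
    process; otherwise events are homogeneous Poisson at cfg.firing_rate.
    """
    if event_times is None:
        n_events = rng.poisson(cfg.firing_rate * cfg.duration)
        event_times = np.sort(rng.integers(0, n_samples, size=n_events))
    spikes = []
    for e in event_times:
        spikes.append(e)
        if cfg.burst_size > 1 and rng.random() < cfg.burst_prob:
            t = e
            for _ in range(cfg.burst_size - 1):
                isi = rng.uniform(*BURST_ISI_MS) * 1e-3 * cfg.fs
                t = t + isi
                spikes.append(int(round(t)))
    spikes = np.sort(np.asarray(spikes, dtype=int))
    # absolute refractory period
    refr = int(round(REFRACTORY_MS * 1e-3 * cfg.fs))
    kept = []
    last = -np.inf
    for s in spikes:
        if s - last >= refr:
            kept.append(s)
            last = s
    kept = np.asarray(kept, dtype=int)
    # drop spikes whose template support would exceed the trace
    lo, hi = margin
    return kept[(kept >= lo) & (kept < n_samples - hi)]


def _render_channel(
    templates: list[dict], spike_times: list[np.ndarray], n_samples: int
) -> np.ndarray:
    clean = np.zeros(n_samples)
    for tpl, times in zip(templates, spike_times):
        wave, peak = tpl["waveform"], tpl["peak"]
        for s in times:
            start = s - peak
            clean[start : start + len(wave)] += wave
    return clean


def _lfp(rng: np.random.Generator, cfg: SynthConfig, n_samples: int) -> np.ndarray:
    t = np.arange(n_samples) / cfg.fs
    out = np.zeros(n_samples)
    for f, a in cfg.lfp_components:
        out += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def _noise(rng: np.random.Generator, cfg: SynthConfig, n_samples: int) -> np.ndarray:
    x = rng.normal(0.0, cfg.noise_sigma, size=n_samples)
    if cfg.noise_one_over_f:
        # shape the spectrum as 1/sqrt(f) in amplitude, renormalized to sigma
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(n_samples, d=1.0 / cfg.fs)
        f[0] = f[1] if len(f) > 1 else 1.0
        spec *= 1.0 / np.sqrt(f)
        x = np.fft.irfft(spec, n=n_samples)
        x *= cfg.noise_sigma / x.std()
    return x


def generate_recording(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Deterministic under cfg.seed: trace = spikes + LFP + noise."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration * cfg.fs))
    tps = cfg.resolved_templates()
    templates = make_templates(tps, cfg.fs)
    margins = [(t["peak"], len(t["waveform"]) - t["peak"]) for t in templates]

    signal = np.zeros((cfg.n_channels, n_samples))
    clean = np.zeros_like(signal)
    noise = np.zeros_like(signal)
    lfp = np.zeros_like(signal)
    spike_times: list[list[np.ndarray]] = []
    unit_ids: list[list[int]] = []
    for ch in range(cfg.n_channels):
        ch_times = [
            _unit_spike_times(rng, cfg, n_samples, margins[u])
            for u in range(cfg.units_per_channel)
        ]
        spike_times.append(ch_times)
        unit_ids.append(list(range(cfg.units_per_channel)))
        clean[ch] = _render_channel(templates, ch_times, n_samples)
        lfp[ch] = _lfp(rng, cfg, n_samples)
        noise[ch] = _noise(rng, cfg, n_samples)
        signal[ch] = clean[ch] + lfp[ch] + noise[ch]

    rec = Recording(signal.astype(np.float64), cfg.fs,
                    channel_ids=list(range(cfg.n_channels)),
                    meta={"source": "synthio", "seed": cfg.seed, "units": "uV"})
    gt = GroundTruth(spike_times, unit_ids, clean, noise, lfp, cfg.fs)
    return rec, gt


def generate_population(cfg: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Multichannel recording with specified pairwise co-firing.

    cfg.correlation[i, j] = p means channels i and j share a fraction ≈ p of
    their spike events (shared events jittered by < 5 ms).  Construction:
    one shared Poisson source of rate p*r per correlated pair plus an
    independent source making each channel's total event rate r.  The summed
    shared fractions per channel must not exceed 1.
    """
    cfg.validate()
    if cfg.correlation is None:
        return generate_recording(cfg)
    corr = np.asarray(cfg.correlation, dtype=float)
    k = cfg.n_channels
    if corr.shape != (k, k) or not np.allclose(corr, corr.T):
        raise ValueError("correlation matrix must be symmetric n_channels x n_channels")
    if np.any((corr < 0) | (corr > 1)):
        raise ValueError("co-firing probabilities must lie in [0, 1]")
    shared_load = corr.sum(axis=1) - np.diag(corr)
    if np.any(shared_load > 1 + 1e-9):
        raise ValueError("summed pairwise co-firing exceeds 1 for some channel")

    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration * cfg.fs))
    tps = cfg.resolved_templates()
    templates = make_templates(tps, cfg.fs)
    margins = [(t["peak"], len(t["waveform"]) - t["peak"]) for t in templates]
    # each channel is jittered by less than half the bound so the *pairwise*
    # offset of a shared event stays below cofire_jitter_ms
    jitter = max(0, int(round(cfg.cofire_jitter_ms * 1e-3 * cfg.fs)) // 2 - 1)

    events = [[] for _ in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            p = corr[i, j]
            if p <= 0:
                continue
            n_shared = rng.poisson(p * cfg.firing_rate * cfg.duration)
            src = rng.integers(0, n_samples, size=n_shared)
            for ch in (i, j):
                jit = rng.integers(-jitter, jitter + 1, size=n_shared) if jitter else 0
                events[ch].append(np.clip(src + jit, 0, n_samples - 1))
    signal = np.zeros((k, n_samples))
    clean = np.zeros_like(signal)
    noise = np.zeros_like(signal)
    lfp = np.zeros_like(signal)
    spike_times: list[list[np.ndarray]] = []
    unit_ids: list[list[int]] = []
    for ch in range(k):
        indep_rate = cfg.firing_rate * (1.0 - shared_load[ch])
        n_indep = rng.poisson(max(indep_rate, 0.0) * cfg.duration)
        events[ch].append(rng.integers(0, n_samples, size=n_indep))
        ev = np.sort(np.concatenate(events[ch])) if events[ch] else np.array([], int)
        times = _unit_spike_times(rng, cfg, n_samples, margins[0], event_times=ev)
        spike_times.append([times])
        unit_ids.append([0])
        clean[ch] = _render_channel(templates[:1], [times], n_samples)
        lfp[ch] = _lfp(rng, cfg, n_samples)
        noise[ch] = _noise(rng, cfg, n_samples)
        signal[ch] = clean[ch] + lfp[ch] + noise[ch]

    rec = Recording(signal, cfg.fs, channel_ids=list(range(k)),
                    meta={"source": "synthio.population", "seed": cfg.seed,
                          "units": "uV"})
    gt = GroundTruth(spike_times, unit_ids, clean, noise, lfp, cfg.fs)
    return rec, gt
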