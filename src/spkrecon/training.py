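"""Spike-focused window selection (SFWS), supervised training, and sliding-
window full-trace reconstruction.

SFWS builds each minibatch of B windows so that the first B/2 are anchored on
a ground-truth spike's negative peak with an integer jitter τ drawn uniformly
from (-W/2, W/2]; the window [n + τ - W/2, n + τ + W/2) then always contains
the peak, at a uniformly distributed position.  The second half of the batch
is sampled uniformly from all electrodes and positions.  Training minimizes
the mean squared error between the network output and the normalized
high-band ground-truth window (Adam, fixed learning rate).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .dsp import NormalizedPair, estimate_noise_sigma
from .metrics import DetectionParams, detect_spikes
from .model import forward_window
from .nn.autograd import Tensor
from .nn.optim import Adam


@dataclass
class TrainConfig:
    B: int = 16            # batch size
    W: int = 128           # window length (samples); equals the model's T
    epochs: int = 200
    steps_per_epoch: int = 100
    lr: float = 1e-4
    stride: int = 64       # evaluation hop
    M: int = 8             # downsampling factor this model serves
    sfws: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.sfws and self.B % 2:
            raise ValueError("batch size must be even when SFWS is on")
        if self.stride > self.W or self.stride < 1:
            raise ValueError("stride must lie in [1, W]")


@dataclass
class SpikeIndex:
    """Per electrode k: the normalized GT trace, its spike count and the peak
    sample positions (minima of detected spike waveforms)."""

    traces: list[np.ndarray]
    peaks: list[np.ndarray]

    @property
    def n_electrodes(self) -> int:
        return len(self.traces)

    @property
    def total_spikes(self) -> int:
        return int(sum(len(p) for p in self.peaks))


@dataclass
class SfwsBatch:
    inputs: np.ndarray     # (B, W)
    targets: np.ndarray    # (B, W)
    anchors: list[tuple[int, int, int]]  # (electrode, spike index, jitter) for first half


def index_spikes(pairs: list[NormalizedPair],
                 params: DetectionParams | None = None) -> SpikeIndex:
    """Detect ground-truth spike peaks on each electrode's high-band trace.

    The noise SD is estimated per electrode from the trace itself; peaks are
    the per-event minima from the threshold detector.
    """
    traces, peaks = [], []
    for p in pairs:
        sigma = estimate_noise_sigma(p.hpf_gt)
        if sigma <= 0:
            raise ValueError("zero noise SD on an electrode; cannot index spikes")
        traces.append(np.asarray(p.hpf_gt))
        peaks.append(detect_spikes(p.hpf_gt, sigma, params, fs=p.fs))
    return SpikeIndex(traces, peaks)


def sample_sfws_batch(index: SpikeIndex, pairs: list[NormalizedPair],
                      cfg: TrainConfig, rng: np.random.Generator) -> SfwsBatch:
    """Draw one training batch.

    With SFWS on: first B/2 windows anchored on uniformly chosen (electrode,
    spike) with jitter τ ~ U{-W/2+1, ..., W/2}; remaining windows uniform.
    Windows that would cross a trace boundary are redrawn.
    """
    cfg.validate()
    w = cfg.W
    half = w // 2
    n_anchor = cfg.B // 2 if cfg.sfws else 0
    if cfg.sfws:
        anchored = [(k, i) for k in range(index.n_electrodes)
                    for i in range(len(index.peaks[k]))]
        if not anchored:
            raise ValueError("SFWS requires at least one indexed spike")
    for p in pairs:
        if len(p.hpf_gt) < w:
            raise ValueError("trace shorter than the window length")

    inputs = np.empty((cfg.B, w))
    targets = np.empty((cfg.B, w))
    anchors: list[tuple[int, int, int]] = []
    j = 0
    while j < n_anchor:
        k, i = anchored[rng.integers(len(anchored))]
        tau = int(rng.integers(-half + 1, half + 1))   # (-W/2, W/2]
        n = int(index.peaks[k][i])
        start = n + tau - half
        if start < 0 or start + w > len(index.traces[k]):
            continue
        inputs[j] = pairs[k].lpf_input[start : start + w]
        targets[j] = pairs[k].hpf_gt[start : start + w]
        anchors.append((k, i, tau))
        j += 1
    while j < cfg.B:
        k = int(rng.integers(index.n_electrodes))
        start = int(rng.integers(0, len(index.traces[k]) - w + 1))
        inputs[j] = pairs[k].lpf_input[start : start + w]
        targets[j] = pairs[k].hpf_gt[start : start + w]
        j += 1
    return SfwsBatch(inputs, targets, anchors)


def train_model(network, pairs: list[NormalizedPair], cfg: TrainConfig,
                index: SpikeIndex | None = None,
                checkpoint_path: str | None = None,
                log_every: int = 0) -> list[float]:
    """Minimize MSE between reconstructed and ground-truth windows.

    Returns the per-epoch mean loss history.  Deterministic under cfg.seed.
    """
    cfg.validate()
    if index is None:
        index = index_spikes(pairs)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(network.parameters(), lr=cfg.lr)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        losses = []
        for step in range(cfg.steps_per_epoch):
            batch = sample_sfws_batch(index, pairs, cfg, rng)
            x = Tensor(batch.inputs[:, :, None])
            y = batch.targets[:, :, None]
            pred = network(x)
            err = pred - y
            loss = (err * err).mean()
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if log_every and (epoch + 1) % log_every == 0:
            print(f"epoch {epoch + 1}/{cfg.epochs}  mse {history[-1]:.6f}")
    if checkpoint_path is not None:
        from .model import save_checkpoint

        save_checkpoint(network, checkpoint_path)
    return history


def write_loss_history(history: list[float], path: str) -> None:
    with open(path, "w", newline="") as f:
        wtr = csv.writer(f)
        wtr.writerow(["epoch", "mean_mse"])
        for i, v in enumerate(history):
            wtr.writerow([i, f"{v:.10g}"])


def reconstruct_sequence(network, interpolated_lpf: np.ndarray,
                         cfg: TrainConfig | None = None,
                         batch_windows: int = 256) -> np.ndarray:
    """Reconstruct a full trace by sliding a W-sample window at `stride`.

    Overlapping predictions are averaged sample-wise; the final window is
    right-aligned to the trace end so every sample is covered.  Output length
    equals input length.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(interpolated_lpf, dtype=np.float64)
    n, w, s = len(x), cfg.W, cfg.stride
    if n < w:
        raise ValueError("trace shorter than the window length")
    starts = list(range(0, n - w + 1, s))
    if starts[-1] != n - w:
        starts.append(n - w)
    out = np.zeros(n)
    cover = np.zeros(n)
    for b0 in range(0, len(starts), batch_windows):
        chunk = starts[b0 : b0 + batch_windows]
        wins = np.stack([x[st : st + w] for st in chunk])
        preds = forward_window(network, wins)
        for st, p in zip(chunk, preds):
            out[st : st + w] += p
            cover[st : st + w] += 1
    return out / cover
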