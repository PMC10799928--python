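"""Spike-train and signal-level analyses: rate histograms, Pearson
correlation matrices (functional connectivity), PCA + K-Means spike sorting
with best-permutation accuracy, and an STFT spectrogram of the low-band
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


@dataclass
class SpectrogramSpec:
    """Defaults match low-band analysis at 3125 Hz: Hamming window of 1250
    samples with 1125-sample overlap (hop = 125 samples = 40 ms).  n_freq
    optionally fixes the number of one-sided frequency bins (the transform
    length is then 2*(n_freq - 1)); by default the transform length equals
    the window length."""

    fs: float = 3125.0
    window: int = 1250
    overlap: int = 1125
    n_freq: int | None = None

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 <= self.overlap < self.window:
            raise ValueError("overlap must satisfy 0 <= overlap < window")


@dataclass
class SortingResult:
    pc_scores: np.ndarray    # (n_spikes, 2)
    labels: np.ndarray
    k: int
    degenerate: bool = False


def rate_histogram(spike_times: np.ndarray, duration_s: float, fs: float,
                   bin_ms: float = 50.0) -> np.ndarray:
    """Spike counts in half-open [i*bin, (i+1)*bin) bins over [0, duration)."""
    t = np.asarray(spike_times, dtype=float) / fs
    if t.size and (t.min() < 0 or t.max() >= duration_s):
        raise ValueError("spike times must lie in [0, duration)")
    n_bins = int(np.ceil(duration_s / (bin_ms * 1e-3)))
    edges = np.arange(n_bins + 1) * bin_ms * 1e-3
    counts, _ = np.histogram(t, bins=edges)
    return counts


def correlation_matrix(trains: list[np.ndarray], duration_s: float, fs: float,
                       bin_ms: float = 50.0) -> np.ndarray:
    """Pearson correlation of per-electrode rate histograms.

    Entries involving a constant (e.g. empty) histogram are NaN; the
    diagonal is 1 by definition.
    """
    if len(trains) < 2:
        raise ValueError("need at least two electrodes")
    hists = np.stack([rate_histogram(t, duration_s, fs, bin_ms) for t in trains])
    if hists.shape[1] < 2:
        raise ValueError("need at least two bins")
    sd = hists.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(hists)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def sort_spikes(waveforms: np.ndarray, k: int = 2, seed: int = 0) -> SortingResult:
    """Project centered waveforms on the first two principal components and
    cluster the (PC1, PC2) scores with K-Means (k-means++, fixed seed)."""
    w = np.asarray(waveforms, dtype=float)
    if w.ndim != 2:
        raise ValueError("waveforms must be a (n_spikes, n_samples) array")
    if k > len(w):
        raise ValueError(f"k={k} exceeds the number of spikes ({len(w)})")
    if k not in (2, 3):
        raise ValueError("cluster count is 2 or 3")
    pca = PCA(n_components=2, random_state=seed)
    scores = pca.fit_transform(w)
    degenerate = bool(np.allclose(scores, 0))
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(scores)
    return SortingResult(scores, labels, k, degenerate)


def clustering_accuracy(pred_labels: np.ndarray, ref_labels: np.ndarray) -> float:
    """Best-permutation agreement fraction between two labelings (optimal
    assignment over the label contingency table)."""
    pred = np.asarray(pred_labels)
    ref = np.asarray(ref_labels)
    if pred.shape != ref.shape:
        raise ValueError("label vectors must have equal length")
    pu, pi = np.unique(pred, return_inverse=True)
    ru, ri = np.unique(ref, return_inverse=True)
    n = max(len(pu), len(ru))
    cont = np.zeros((n, n))
    np.add.at(cont, (pi, ri), 1)
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / len(pred))


def spectrogram(signal: np.ndarray,
                spec: SpectrogramSpec | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier power of a 1D signal.

    Returns (freqs_hz, frame_times_s, power) where power[f, t] = |X[f]|² of
    the Hamming-windowed frame.  Frames advance by window - overlap samples;
    frequencies are one-sided.
    """
    spec = spec or SpectrogramSpec()
    spec.validate()
    x = np.asarray(signal, dtype=float)
    if len(x) < spec.window:
        raise ValueError("signal shorter than the analysis window")
    hop = spec.window - spec.overlap
    n_frames = 1 + (len(x) - spec.window) // hop
    win = sps.windows.hamming(spec.window, sym=True)
    nfft = spec.window if spec.n_freq is None else 2 * (spec.n_freq - 1)
    frames = np.stack([x[i * hop : i * hop + spec.window] * win
                       for i in range(n_frames)])
    spec_c = np.fft.rfft(frames, n=max(nfft, spec.window), axis=1)
    if spec.n_freq is not None:
        spec_c = spec_c[:, : spec.n_freq]
    power = np.abs(spec_c) ** 2
    freqs = np.arange(power.shape[1]) * spec.fs / max(nfft, spec.window)
    times = (np.arange(n_frames) * hop + spec.window / 2) / spec.fs
    return freqs, times, power.T
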