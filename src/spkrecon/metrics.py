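"""Spike detection, train matching, and waveform-level scores.

Detection follows the standard negative-threshold convention: samples
crossing -6 SD of the background noise of the ground-truth trace open an
event; excursions closer than a dead time are merged; the event's timestamp
is the sample of its minimum.  Reconstructed timestamps within ±500 μs of a
ground-truth timestamp count as correctly restored; matching is one-to-one
and of maximum cardinality.  Waveform fidelity is scored on -1 to +2 ms
windows around the ground-truth timestamps, as RMSE normalized by the
window's peak-to-peak amplitude (NRMSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DetectionParams:
    k_sigma: float = -6.0    # threshold multiple of the noise SD (negative)
    dead_time_ms: float = 1.0
    # timestamps are aligned to the local minimum within each event

    def validate(self) -> None:
        if self.k_sigma >= 0:
            raise ValueError("k_sigma must be negative (negative-peak detection)")
        if self.dead_time_ms <= 0:
            raise ValueError("dead_time must be positive")


@dataclass
class WaveformWindow:
    pre_ms: float = 1.0
    post_ms: float = 2.0

    def sample_span(self, fs: float) -> tuple[int, int]:
        return int(round(self.pre_ms * 1e-3 * fs)), int(round(self.post_ms * 1e-3 * fs))


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]          # (gt_sample, rec_sample)
    fp_times: np.ndarray
    fn_times: np.ndarray
    tolerance_us: float
    fs: float
    delays_us: np.ndarray = field(init=False)

    def __post_init__(self):
        self.delays_us = np.array(
            [(r - g) * 1e6 / self.fs for g, r in self.pairs], dtype=float
        )

    @property
    def n_tp(self) -> int:
        return len(self.pairs)

    @property
    def hit_rate(self) -> float:
        denom = self.n_tp + len(self.fn_times)
        return self.n_tp / denom if denom else float("nan")

    @property
    def precision(self) -> float:
        denom = self.n_tp + len(self.fp_times)
        return self.n_tp / denom if denom else float("nan")


def detect_spikes(signal: np.ndarray, sigma: float,
                  params: DetectionParams | None = None,
                  fs: float = 25_000.0) -> np.ndarray:
    """Timestamps (sample indices) of threshold-crossing events.

    Contiguous sub-threshold excursions separated by less than the dead time
    are merged into one event; each event's timestamp is its minimum sample.
    """
    params = params or DetectionParams()
    params.validate()
    if sigma <= 0:
        raise ValueError("noise sigma must be positive")
    x = np.asarray(signal, dtype=np.float64)
    thr = params.k_sigma * sigma
    below = x < thr
    if not below.any():
        return np.array([], dtype=int)
    d = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, len(x)]
    dead = int(round(params.dead_time_ms * 1e-3 * fs))
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < dead:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return np.array([s + int(np.argmin(x[s:e])) for s, e in merged], dtype=int)


def _check_sorted(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.size > 1 and np.any(np.diff(a) < 0):
        raise ValueError(f"{name} timestamps must be sorted")
    return a


def match_trains(gt_times: np.ndarray, rec_times: np.ndarray,
                 fs: float, tolerance_us: float = 500.0) -> MatchResult:
    """One-to-one maximum-cardinality matching within ±tolerance.

    Both trains sorted.  Each reconstructed timestamp, in order, is matched
    to the earliest unmatched ground-truth timestamp within tolerance
    (earliest-deadline greedy — optimal for equal-length tolerance windows,
    i.e. it attains the maximum possible number of true positives).
    """
    gt = _check_sorted(gt_times, "gt")
    rec = _check_sorted(rec_times, "rec")
    tol = tolerance_us * 1e-6 * fs
    pairs: list[tuple[int, int]] = []
    matched_gt = np.zeros(len(gt), dtype=bool)
    matched_rec = np.zeros(len(rec), dtype=bool)
    lo = 0
    for j, r in enumerate(rec):
        while lo < len(gt) and (matched_gt[lo] or gt[lo] < r - tol):
            lo += 1
        # earliest unmatched gt with gt >= r - tol; also require gt <= r + tol
        i = lo
        while i < len(gt) and gt[i] <= r + tol and matched_gt[i]:
            i += 1
        if i < len(gt) and gt[i] <= r + tol:
            matched_gt[i] = True
            matched_rec[j] = True
            pairs.append((int(gt[i]), int(r)))
    fp = np.asarray(rec)[~matched_rec].astype(int)
    fn = np.asarray(gt)[~matched_gt].astype(int)
    return MatchResult(pairs, fp, fn, tolerance_us, fs)


def mean_time_delay(match: MatchResult) -> float:
    """Mean signed delay (reconstructed - ground truth) of matched spikes, μs."""
    if match.n_tp == 0:
        raise ValueError("no matched spikes; mean delay undefined")
    return float(np.mean(match.delays_us))


def extract_windows(trace: np.ndarray, times: np.ndarray, window: WaveformWindow,
                    fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Stack -pre..+post ms windows around `times`; drops timestamps without
    full support.  Returns (windows, kept_times)."""
    pre, post = window.sample_span(fs)
    trace = np.asarray(trace)
    keep = [t for t in np.asarray(times, dtype=int)
            if t - pre >= 0 and t + post <= len(trace)]
    if not keep:
        return np.empty((0, pre + post)), np.array([], dtype=int)
    w = np.stack([trace[t - pre : t + post] for t in keep])
    return w, np.asarray(keep, dtype=int)


def waveform_nrmse(gt_trace: np.ndarray, rec_trace: np.ndarray,
                   matched_gt_times: np.ndarray,
                   window: WaveformWindow | None = None,
                   fs: float = 25_000.0) -> tuple[np.ndarray, float]:
    """Per-spike NRMSE over matched ground-truth timestamps, plus the mean.

    NRMSE = RMSE(gt window, rec window) / peak-to-peak(gt window); windows
    span -pre..+post ms around each ground-truth timestamp.  Spikes whose
    ground-truth window is flat are skipped.
    """
    window = window or WaveformWindow()
    gw, kept = extract_windows(gt_trace, matched_gt_times, window, fs)
    rw, _ = extract_windows(rec_trace, matched_gt_times, window, fs)
    vals = []
    for g, r in zip(gw, rw):
        ptp = float(np.ptp(g))
        if ptp == 0:
            import warnings

            warnings.warn("flat ground-truth window skipped in NRMSE")
            continue
        vals.append(float(np.sqrt(np.mean((g - r) ** 2)) / ptp))
    arr = np.asarray(vals)
    return arr, (float(arr.mean()) if arr.size else float("nan"))


def average_waveform(trace: np.ndarray, matched_times: np.ndarray,
                     window: WaveformWindow | None = None,
                     fs: float = 25_000.0) -> np.ndarray:
    """Sample-wise mean of windows aligned on the ground-truth timestamps."""
    window = window or WaveformWindow()
    w, kept = extract_windows(trace, matched_times, window, fs)
    if len(w) == 0:
        raise ValueError("no spikes with full window support")
    return w.mean(axis=0)
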