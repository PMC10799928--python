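"""Band splitting, subsampling, Fourier re-interpolation, pair normalization.

The preprocessing chain mirrors the acquisition model: a wideband trace is
split into a low-frequency (LFP-band) component and a high-frequency (spike
band) component with zero-phase fourth-order Butterworth filters at 200 Hz;
the low band is subsampled by an integer factor M (no extra anti-aliasing —
the preceding low-pass is the band limit) and re-upsampled by L = M with the
Fourier (FFT zero-padding) method so the network input has the same temporal
resolution as the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

DEFAULT_CUTOFF_HZ = 200.0
DEFAULT_ORDER = 4


@dataclass
class FilterSpec:
    order: int = DEFAULT_ORDER
    cutoff: float = DEFAULT_CUTOFF_HZ
    kind: str = "lowpass"            # 'lowpass' | 'highpass'
    mode: str = "zero_phase"         # 'zero_phase' | 'ideal_brickwall'

    def validate(self, fs: float) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.cutoff < fs / 2:
            raise ValueError(f"cutoff {self.cutoff} Hz must lie in (0, fs/2={fs/2})")
        if self.kind not in ("lowpass", "highpass"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.mode not in ("zero_phase", "ideal_brickwall"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ResampleSpec:
    """Downsampling factor M and interpolation factor L (L = M unless set)."""

    M: int = 1
    L: int | None = None

    def __post_init__(self):
        if int(self.M) != self.M or self.M < 1:
            raise ValueError("M must be a positive integer")
        self.M = int(self.M)
        if self.L is None:
            self.L = self.M
        elif int(self.L) != self.L or self.L < 1:
            raise ValueError("L must be a positive integer")
        else:
            self.L = int(self.L)


@dataclass
class NormalizedPair:
    """Aligned (interpolated low-band input, high-band ground truth) pair for
    one electrode, both divided by the same scale (μV)."""

    lpf_input: np.ndarray
    hpf_gt: np.ndarray
    scale: float
    fs: float
    electrode_id: int | str = 0

    def to_physical(self) -> tuple[np.ndarray, np.ndarray]:
        return self.lpf_input * self.scale, self.hpf_gt * self.scale


def _apply_filter(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    spec.validate(fs)
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if spec.mode == "zero_phase":
        if x.shape[-1] <= 3 * spec.order:
            raise ValueError("signal too short for the requested filter order")
        sos = sps.butter(spec.order, spec.cutoff, btype=spec.kind, fs=fs, output="sos")
        return sps.sosfiltfilt(sos, x, axis=-1)
    # ideal brick wall: zero the Fourier coefficients outside the band;
    # the bin at the cutoff goes to the lowpass side so LPF+HPF partition
    # the spectrum exactly
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec_x = np.fft.rfft(x, axis=-1)
    keep = freqs <= spec.cutoff if spec.kind == "lowpass" else freqs > spec.cutoff
    spec_x = np.where(keep, spec_x, 0.0)
    return np.fft.irfft(spec_x, n=n, axis=-1)


def butterworth_split(
    x: np.ndarray,
    fs: float,
    order: int = DEFAULT_ORDER,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    mode: str = "zero_phase",
) -> tuple[np.ndarray, np.ndarray]:
    """Split a trace into (lpf, hpf) at `cutoff` Hz.

    mode='zero_phase': forward-backward Butterworth (magnitude response |H|²,
    zero phase); the low/high pair is power-complementary, so lpf + hpf
    reproduces the input away from the edges.
    mode='ideal_brickwall': exact spectral partition via FFT masking.
    """
    lo = _apply_filter(x, fs, FilterSpec(order, cutoff, "lowpass", mode))
    hi = _apply_filter(x, fs, FilterSpec(order, cutoff, "highpass", mode))
    return lo, hi


def downsample(x: np.ndarray, M: int) -> np.ndarray:
    """Keep every M-th sample (indices 0, M, 2M, ...). The preceding
    low-pass filter is the only anti-aliasing, by design."""
    if int(M) != M or M < 1:
        raise ValueError("M must be a positive integer")
    return np.asarray(x)[..., :: int(M)]


def fourier_resample(x: np.ndarray, L: int) -> np.ndarray:
    """Fourier-method interpolation to length L*N (FFT zero padding).

    The original samples reappear exactly at stride L in the output.
    """
    if int(L) != L or L < 1:
        raise ValueError("L must be a positive integer")
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if n == 0:
        raise ValueError("cannot resample an empty signal")
    if L == 1:
        return x.copy()
    return sps.resample(x, int(L) * n, axis=-1)


def estimate_noise_sigma(hpf: np.ndarray) -> float:
    """Robust noise SD of a high-band trace: median(|x|)/0.6745.

    The normal-consistent median absolute deviation is nearly unaffected by
    sparse large spikes, unlike the plain standard deviation.
    """
    return float(np.median(np.abs(np.asarray(hpf))) / 0.6745)


def background_mask(
    hpf: np.ndarray, fs: float, sigma: float | None = None,
    k_sigma: float = 5.0, guard_ms: float = 2.0,
) -> np.ndarray:
    """Boolean mask of spike-free samples: everything farther than `guard_ms`
    from any crossing of -k_sigma*sigma."""
    hpf = np.asarray(hpf)
    if sigma is None:
        sigma = estimate_noise_sigma(hpf)
    mask = np.ones(hpf.shape[-1], dtype=bool)
    if sigma <= 0:
        return mask
    crossings = np.flatnonzero(hpf < -k_sigma * sigma)
    guard = int(round(guard_ms * 1e-3 * fs))
    for c in crossings:
        mask[max(0, c - guard) : c + guard + 1] = False
    return mask


def normalize_pair(
    lpf_interp: np.ndarray,
    hpf: np.ndarray,
    fs: float,
    electrode_id: int | str = 0,
) -> NormalizedPair:
    """Divide both sequences by the maximum absolute value of the background
    noise of the high-band trace (spike-free samples only)."""
    lpf_interp = np.asarray(lpf_interp, dtype=np.float64)
    hpf = np.asarray(hpf, dtype=np.float64)
    if lpf_interp.shape != hpf.shape:
        raise ValueError("input and ground-truth sequences must have equal length")
    mask = background_mask(hpf, fs)
    quiet = hpf[..., mask] if hpf.ndim == 1 else hpf[:, mask]
    scale = float(np.max(np.abs(quiet))) if quiet.size else 0.0
    if scale <= 0:
        raise ValueError("background noise amplitude is zero; cannot normalize")
    return NormalizedPair(lpf_interp / scale, hpf / scale, scale, fs, electrode_id)


def preprocess_trace(
    x: np.ndarray,
    fs: float,
    M: int,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    mode: str = "zero_phase",
    electrode_id: int | str = 0,
) -> NormalizedPair:
    """Full chain for one trace: band split -> subsample by M -> Fourier
    re-interpolate by L = M -> normalize the pair."""
    n = np.asarray(x).shape[-1]
    trim = n - (n % M)
    x = np.asarray(x)[..., :trim]  # make the length divisible by M
    lpf, hpf = butterworth_split(x, fs, order=order, cutoff=cutoff, mode=mode)
    lpf_interp = fourier_resample(downsample(lpf, M), M)
    return normalize_pair(lpf_interp, hpf, fs, electrode_id)
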