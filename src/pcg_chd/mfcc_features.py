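"""Mel-frequency cepstral coefficients (MFCC) for heart-sound recordings.

Processing chain per frame: pre-emphasis y[t] = x[t] - alpha*x[t-1] ->
Hamming window -> magnitude-squared FFT -> triangular mel filterbank ->
log(energy + eps) -> orthonormal DCT-II; the first ``n_coeffs`` cepstral
coefficients are kept and averaged over frames into one descriptor per
recording.

The mel scale maps linear frequency to perceptual pitch:

    mel(f) = 2595 * log10(1 + f / 700)

Framing uses a 30 ms window with a 10 ms hop (20 ms overlap) by default;
at 44.1 kHz that is the 1323-sample Hamming window. All frames lie fully
inside the signal (no padding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft

_LOG_EPS = 1e-12  # floor inside the log so silent frames stay finite


@dataclass
class MfccConfig:
    win_ms: float = 30.0
    hop_ms: float = 10.0
    preemphasis: float = 0.97
    n_filters: int = 26
    n_coeffs: int = 13
    fft_size: int | None = None  # None: next power of two >= window length
    fmin: float = 0.0
    fmax: float | None = None  # None: Nyquist
    include_c0: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.hop_ms <= self.win_ms:
            raise ValueError("need 0 < hop_ms <= win_ms")
        if not 0 <= self.preemphasis < 1:
            raise ValueError("pre-emphasis coefficient must lie in [0, 1)")
        if self.n_coeffs > self.n_filters:
            raise ValueError("cannot keep more cepstral coefficients than filters")

    def win_length(self, fs: float) -> int:
        return int(round(self.win_ms * fs / 1000.0))

    def hop_length(self, fs: float) -> int:
        return int(round(self.hop_ms * fs / 1000.0))

    def resolve_fft_size(self, fs: float) -> int:
        if self.fft_size is not None:
            return self.fft_size
        return 1 << (self.win_length(fs) - 1).bit_length()


@dataclass
class MfccFeatures:
    """Per-recording cepstral descriptor (frame-averaged coefficients)."""

    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("cepstral coefficients must be finite")


def mel_scale(f):
    """Hz -> mel, mel(f) = 2595*log10(1 + f/700); strictly increasing."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_to_hz(m):
    """Inverse of :func:`mel_scale`."""
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def frame_signal(signal: np.ndarray, fs: float, cfg: MfccConfig | None = None) -> np.ndarray:
    """Slice into overlapping frames, pre-emphasize, and apply a Hamming window.

    Returns an (n_frames, win_length) array; raises if the signal is shorter
    than one window.
    """
    cfg = cfg or MfccConfig()
    x = np.asarray(signal, dtype=np.float64)
    win = cfg.win_length(fs)
    hop = cfg.hop_length(fs)
    if x.size < win:
        raise ValueError(f"signal ({x.size} samples) shorter than one {win}-sample window")
    n_frames = (x.size - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    # per-frame first-difference pre-emphasis; the first sample is kept as-is
    emph = frames.copy()
    emph[:, 1:] -= cfg.preemphasis * frames[:, :-1]
    return emph * np.hamming(win)


def mel_filterbank(cfg: MfccConfig, fs: float, n_fft: int | None = None) -> np.ndarray:
    """Triangular mel filterbank as an (n_filters, n_fft//2 + 1) matrix.

    Filter centers are equally spaced on the mel axis between ``fmin`` and
    ``fmax``; each filter rises linearly from the previous center to its own
    and falls to the next, evaluated at the FFT bin frequencies.
    """
    n_fft = n_fft or cfg.resolve_fft_size(fs)
    fmax = cfg.fmax if cfg.fmax is not None else fs / 2.0
    if fmax > fs / 2.0 + 1e-9:
        raise ValueError("fmax exceeds the Nyquist frequency")
    edges_hz = mel_to_hz(np.linspace(mel_scale(cfg.fmin), mel_scale(fmax), cfg.n_filters + 2))
    bin_freqs = np.arange(n_fft // 2 + 1) * fs / n_fft
    center_bins = np.searchsorted(bin_freqs, edges_hz[1:-1])
    if np.any(np.diff(center_bins) < 1):
        raise ValueError(
            f"{cfg.n_filters} filters collapse onto shared FFT bins at "
            f"n_fft={n_fft}; reduce n_filters or increase fft_size"
        )
    fb = np.zeros((cfg.n_filters, bin_freqs.size))
    for j in range(cfg.n_filters):
        lo, mid, hi = edges_hz[j], edges_hz[j + 1], edges_hz[j + 2]
        rising = (bin_freqs - lo) / (mid - lo)
        falling = (hi - bin_freqs) / (hi - mid)
        fb[j] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def extract_mfcc(signal: np.ndarray, fs: float, cfg: MfccConfig | None = None) -> MfccFeatures:
    """Recording-level MFCC descriptor: per-frame cepstra averaged over frames."""
    cfg = cfg or MfccConfig()
    frames = frame_signal(signal, fs, cfg)
    n_fft = cfg.resolve_fft_size(fs)
    power = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(cfg, fs, n_fft)
    log_energies = np.log(power @ fb.T + _LOG_EPS)
    cepstra = dct(log_energies, type=2, norm="ortho", axis=1)
    if cfg.include_c0:
        kept = cepstra[:, : cfg.n_coeffs]
    else:
        kept = cepstra[:, 1 : cfg.n_coeffs + 1]
    return MfccFeatures(coeffs=kept.mean(axis=0))


FEATURE_NAMES = tuple(f"MFCC_{i:02d}" for i in range(13))
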