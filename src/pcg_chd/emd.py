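"""Empirical mode decomposition (EMD) and IMF-rejection denoising.

EMD expands a signal q(t) into a small set of oscillatory intrinsic mode
functions (IMFs) h_1..h_N, ordered from fastest to slowest, plus a residual
trend r(t):

    q(t) = sum_k h_k(t) + r(t)

Each IMF is obtained by *sifting*: repeatedly subtracting the mean of the
cubic-spline upper and lower envelopes until the iterate is approximately
symmetric about zero.  For heart-sound recordings, the first IMF carries
broadband (sensor/ambient) noise and the last IMFs plus the residual carry
baseline drift, so the denoised signal keeps only the middle modes:

    x(t) = sum_{k=2}^{N-2} h_k(t)

discarding h_1, h_{N-1}, h_N and the residual.

Numerical choices the decomposition itself does not pin down: sifting stops
on the standard Cauchy criterion SD = sum((y_prev - y_new)**2) /
sum(y_prev**2) < sd_threshold (default 0.2, at most ``max_sift_iters``
iterations); envelopes mirror the two extrema nearest each end of the signal
before spline fitting, which suppresses end swings; plateau extrema are
assigned their midpoint index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

DEFAULT_SD_THRESHOLD = 0.2
DEFAULT_MAX_IMFS = 12
DEFAULT_MAX_SIFT_ITERS = 100


class ShallowDecompositionError(ValueError):
    """Raised when fewer than 4 IMFs exist, so the rejection rule keeps nothing."""


@dataclass
class ImfDecomposition:
    """Ordered IMFs plus residual for one signal; ``sum(imfs) + residual == input``."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    sd_threshold: float = DEFAULT_SD_THRESHOLD
    max_imfs: int = DEFAULT_MAX_IMFS

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for h in self.imfs:
            out += h
        return out


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    An extremum is a sign change of the first difference; a run of equal
    values (plateau) flanked by opposite slopes counts once, at its midpoint
    index.  Signal endpoints are never extrema.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 samples to locate extrema")
    dx = np.diff(x)
    nz = np.flatnonzero(dx != 0.0)
    if nz.size < 2:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    s = np.sign(dx[nz])
    turn = np.flatnonzero(s[:-1] != s[1:])
    # plateau spans [nz[i]+1, nz[i+1]]; a single-point extremum is the
    # degenerate plateau where both bounds coincide
    mid = (nz[turn] + 1 + nz[turn + 1]) // 2
    is_max = s[turn] > 0
    return mid[is_max], mid[~is_max]


def _envelope_mean(x: np.ndarray) -> np.ndarray:
    """Mean of the cubic-spline envelopes through maxima and minima.

    The two extrema nearest each end are mirrored about the end sample so
    the splines are anchored beyond the signal's support.
    """
    n = x.size
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise ValueError(
            f"need >= 2 maxima and >= 2 minima to form envelopes "
            f"(found {maxima.size} / {minima.size})"
        )
    t = np.arange(n)

    def _spline(idx: np.ndarray) -> np.ndarray:
        k = min(2, idx.size)
        left = -idx[:k][::-1]                 # mirror about t = 0
        right = 2 * (n - 1) - idx[-k:][::-1]  # mirror about t = n - 1
        knots = np.concatenate([left, idx, right])
        vals = np.concatenate([x[idx[:k]][::-1], x[idx], x[idx[-k:]][::-1]])
        knots, keep = np.unique(knots, return_index=True)
        return CubicSpline(knots, vals[keep])(t)

    return 0.5 * (_spline(maxima) + _spline(minima))


def sift_once(signal: np.ndarray) -> np.ndarray:
    """One sifting step: subtract the envelope mean, y(t) = q(t) - a(t)."""
    x = np.asarray(signal, dtype=np.float64)
    return x - _envelope_mean(x)


def decompose(
    signal: np.ndarray,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_imfs: int = DEFAULT_MAX_IMFS,
    max_sift_iters: int = DEFAULT_MAX_SIFT_ITERS,
) -> ImfDecomposition:
    """Full EMD: extract IMFs by sifting until the residual is a trend.

    Decomposition stops when the running residual has fewer than two maxima
    or two minima (monotonic up to a single bend), or ``max_imfs`` is
    reached.  By construction ``sum(imfs) + residual`` equals the input to
    round-off.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 16:
        raise ValueError("signal too short for spline envelopes (need >= 16 samples)")
    imfs: list[np.ndarray] = []
    residual = x.copy()
    while len(imfs) < max_imfs:
        maxima, minima = find_extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residual
        for _ in range(max_sift_iters):
            try:
                h_new = sift_once(h)
            except ValueError:  # envelope collapsed mid-sift
                break
            denom = float(np.sum(h * h))
            if denom == 0.0:
                h = h_new
                break
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        residual = residual - h
    return ImfDecomposition(
        imfs=imfs, residual=residual, sd_threshold=sd_threshold, max_imfs=max_imfs
    )


def denoise(dec: ImfDecomposition, on_shallow: str = "error") -> np.ndarray:
    """Reconstruct a denoised signal as the sum of IMFs 2..N-2 (1-based).

    The first IMF (broadband noise) and the last two IMFs plus the residual
    (drift / DC offset) are discarded.  With fewer than 4 IMFs the kept
    range is empty; ``on_shallow`` selects between raising
    :class:`ShallowDecompositionError` (default) and returning the original
    signal unchanged (``"passthrough"``).
    """
    n = dec.n_imfs
    if n < 4:
        if on_shallow == "passthrough":
            return dec.reconstruct()
        raise ShallowDecompositionError(
            f"decomposition too shallow: {n} IMFs, need >= 4 for the k=2..N-2 rule"
        )
    kept = dec.imfs[1 : n - 2]  # 1-based IMFs 2..N-2
    return np.sum(kept, axis=0)


def denoise_signal(
    signal: np.ndarray,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_imfs: int = DEFAULT_MAX_IMFS,
    max_sift_iters: int = DEFAULT_MAX_SIFT_ITERS,
    on_shallow: str = "error",
) -> np.ndarray:
    """Convenience wrapper: decompose then apply the IMF-rejection rule."""
    return denoise(
        decompose(signal, sd_threshold, max_imfs, max_sift_iters),
        on_shallow=on_shallow,
    )
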