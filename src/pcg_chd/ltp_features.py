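"""One-dimensional local ternary pattern (1D-LTP) descriptors.

A sliding window of ``2*half_width + 1`` samples is centered on each signal
sample theta.  Every neighbor x_p in the window is coded against a ternary
threshold phi:

    F(x_p) = +1  if x_p >= theta + phi
             -1  if x_p <= theta - phi
              0  otherwise

The ternary vector is split into an *upper* binary pattern (indicator of
F = +1) and a *lower* pattern (indicator of F = -1), each collapsed to an
integer code sum_p S(F(p)) * w_p.  With the standard binary weights
w_p = 2**(p-1) and 8 neighbors, codes span 0..255.  The per-recording
descriptor is a pair of equal-width normalized histograms of the upper and
lower code streams (10 bins each by default, 20 values total).

phi can be given in absolute amplitude units or relative to the signal's
standard deviation (default 0.1 * sd, recomputed per recording), which
keeps the coding comparable across recordings of different loudness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class LtpConfig:
    half_width: int = 4
    phi: float = 0.1
    phi_mode: str = "relative"  # "relative": phi * std(signal); "absolute": phi as-is
    n_bins: int = 10
    weight_convention: str = "standard"  # "standard": 2**(p-1); "literal": 2**p

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.phi_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown phi_mode {self.phi_mode!r}")
        if self.weight_convention not in ("standard", "literal"):
            raise ValueError(f"unknown weight_convention {self.weight_convention!r}")

    @property
    def window_length(self) -> int:
        return 2 * self.half_width + 1

    def weights(self) -> np.ndarray:
        p = np.arange(1, 2 * self.half_width + 1)
        return 2 ** (p - 1) if self.weight_convention == "standard" else 2**p

    def resolve_phi(self, signal: np.ndarray) -> float:
        if self.phi_mode == "absolute":
            return self.phi
        return self.phi * float(np.std(signal))


@dataclass
class LtpFeatures:
    """Normalized histograms of the upper and lower pattern codes."""

    upper_hist: np.ndarray
    lower_hist: np.ndarray

    @property
    def values(self) -> np.ndarray:
        """Concatenated descriptor, upper bins then lower bins (length 2*n_bins)."""
        return np.concatenate([self.upper_hist, self.lower_hist])


def ternary_code(window: np.ndarray, phi: float) -> np.ndarray:
    """Ternary codes {-1, 0, +1} for the neighbors of one odd-length window.

    Neighbors are ordered left frame nearest-to-farthest, then right frame
    nearest-to-farthest (the ordering only matters for code reproducibility;
    histograms are unaffected).
    """
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 1 or w.size < 3 or w.size % 2 == 0:
        raise ValueError("window must be 1-D, odd-length and >= 3 samples")
    c = w.size // 2
    theta = w[c]
    neighbors = np.concatenate([w[:c][::-1], w[c + 1 :]])
    out = np.zeros(neighbors.size, dtype=np.int8)
    out[neighbors - (theta + phi) >= 0] = 1
    out[neighbors - (theta - phi) <= 0] = -1
    return out


def pattern_codes(signal: np.ndarray, cfg: LtpConfig, phi: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower integer codes for every fully interior window (stride 1)."""
    x = np.asarray(signal, dtype=np.float64)
    win = cfg.window_length
    if x.ndim != 1 or x.size < win:
        raise ValueError(f"signal must be 1-D with at least {win} samples")
    if phi is None:
        phi = cfg.resolve_phi(x)

    windows = sliding_window_view(x, win)
    h = cfg.half_width
    theta = windows[:, h]
    # columns reordered to the left-near..left-far, right-near..right-far convention
    order = np.concatenate([np.arange(h - 1, -1, -1), np.arange(h + 1, win)])
    neighbors = windows[:, order]
    lower_mask = neighbors - (theta[:, None] - phi) <= 0
    # at phi = 0 the two inequalities overlap at equality; -1 wins, matching
    # ternary_code, so upper/lower stay mutually exclusive
    upper_mask = (neighbors - (theta[:, None] + phi) >= 0) & ~lower_mask
    w = cfg.weights()
    upper = (upper_mask * w).sum(axis=1)
    lower = (lower_mask * w).sum(axis=1)
    return upper.astype(np.int64), lower.astype(np.int64)


def extract_ltp(signal: np.ndarray, cfg: LtpConfig | None = None) -> LtpFeatures:
    """Full descriptor: code streams binned into equal-width normalized histograms.

    Bins cover the full attainable code range [0, sum(weights)] so the
    descriptor is comparable across recordings; histograms are normalized to
    probability vectors.
    """
    cfg = cfg or LtpConfig()
    upper, lower = pattern_codes(signal, cfg)
    code_max = int(cfg.weights().sum())

    def _hist(codes: np.ndarray) -> np.ndarray:
        counts, _ = np.histogram(codes, bins=cfg.n_bins, range=(0, code_max))
        return counts / codes.size

    return LtpFeatures(upper_hist=_hist(upper), lower_hist=_hist(lower))


FEATURE_NAMES = tuple(
    [f"LTP_U_{i:02d}" for i in range(1, 11)] + [f"LTP_L_{i:02d}" for i in range(1, 11)]
)
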