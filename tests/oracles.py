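"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: plain loops, explicitly
constructed transform matrices, and (for EMD) a different boundary
treatment, so agreement between the two routes is evidence rather than
tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def brute_force_ltp_codes(signal, half_width, phi, weights):
    """Upper/lower pattern codes via an explicit double loop over windows."""
    x = np.asarray(signal, dtype=float)
    win = 2 * half_width + 1
    uppers, lowers = [], []
    for start in range(len(x) - win + 1):
        w = x[start : start + win]
        theta = w[half_width]
        neigh = list(w[:half_width][::-1]) + list(w[half_width + 1 :])
        u = lo = 0
        for p, v in enumerate(neigh):
            if v - (theta - phi) <= 0:
                lo += weights[p]
            elif v - (theta + phi) >= 0:
                u += weights[p]
        uppers.append(u)
        lowers.append(lo)
    return np.array(uppers), np.array(lowers)


def reference_mfcc(signal, fs, win_ms=30.0, hop_ms=10.0, alpha=0.97,
                   n_filters=26, n_coeffs=13, fft_size=None, fmin=0.0, fmax=None):
    """Loop-based MFCC chain with hand-built filterbank and DCT matrix."""
    x = np.asarray(signal, dtype=float)
    win = int(round(win_ms * fs / 1000.0))
    hop = int(round(hop_ms * fs / 1000.0))
    if fft_size is None:
        fft_size = 1
        while fft_size < win:
            fft_size *= 2
    if fmax is None:
        fmax = fs / 2.0

    def mel(f):
        return 2595.0 * np.log10(1.0 + f / 700.0)

    def imel(m):
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)

    edges = imel(np.linspace(mel(fmin), mel(fmax), n_filters + 2))
    bin_f = np.arange(fft_size // 2 + 1) * fs / fft_size
    fb = np.zeros((n_filters, len(bin_f)))
    for j in range(n_filters):
        lo, mid, hi = edges[j], edges[j + 1], edges[j + 2]
        for b, f in enumerate(bin_f):
            if lo <= f <= mid:
                fb[j, b] = (f - lo) / (mid - lo)
            elif mid < f <= hi:
                fb[j, b] = (hi - f) / (hi - mid)

    # orthonormal DCT-II matrix over the M filterbank channels
    M = n_filters
    dct_mat = np.zeros((n_coeffs, M))
    for n in range(n_coeffs):
        for m in range(M):
            dct_mat[n, m] = np.sqrt(2.0 / M) * np.cos(np.pi * n * (m + 0.5) / M)
    dct_mat[0, :] *= 1.0 / np.sqrt(2.0)

    ham = np.hamming(win)
    cepstra = []
    start = 0
    while start + win <= len(x):
        frame = x[start : start + win].copy()
        emph = frame.copy()
        for t in range(win - 1, 0, -1):
            emph[t] = frame[t] - alpha * frame[t - 1]
        spec = np.abs(np.fft.rfft(emph * ham, n=fft_size)) ** 2
        energies = fb @ spec
        cepstra.append(dct_mat @ np.log(energies + 1e-12))
        start += hop
    return np.mean(cepstra, axis=0)


def reference_emd(signal, sd_threshold=0.2, max_imfs=12, max_sift=100):
    """Minimal independent EMD: endpoint-clamped spline envelopes, no mirroring."""
    x = np.asarray(signal, dtype=float)
    n = len(x)

    def extrema(v):
        mx, mn = [], []
        for i in range(1, n - 1):
            if v[i] > v[i - 1] and v[i] > v[i + 1]:
                mx.append(i)
            elif v[i] < v[i - 1] and v[i] < v[i + 1]:
                mn.append(i)
        return np.array(mx, dtype=int), np.array(mn, dtype=int)

    def envelope_mean(v):
        mx, mn = extrema(v)
        if len(mx) < 2 or len(mn) < 2:
            return None
        # clamp: treat both endpoints as knots of each envelope
        tx = np.concatenate([[0], mx, [n - 1]])
        tn = np.concatenate([[0], mn, [n - 1]])
        upper = CubicSpline(tx, v[tx])(np.arange(n))
        lower = CubicSpline(tn, v[tn])(np.arange(n))
        return 0.5 * (upper + lower)

    imfs = []
    resid = x.copy()
    while len(imfs) < max_imfs:
        mx, mn = extrema(resid)
        if len(mx) < 2 or len(mn) < 2:
            break
        h = resid.copy()
        for _ in range(max_sift):
            a = envelope_mean(h)
            if a is None:
                break
            h_new = h - a
            denom = np.sum(h * h)
            if denom == 0:
                h = h_new
                break
            sd = np.sum((h - h_new) ** 2) / denom
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        resid = resid - h
    return imfs, resid
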