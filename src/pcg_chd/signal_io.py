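"""WAV input/output and the in-memory recording container.

A phonocardiogram (PCG) recording is represented as a float array normalized
to [-1, 1] plus its sampling rate.  Normalization divides integer sample
values by the full-scale magnitude of their bit depth (16-bit values by
32768), *not* by the per-file peak, so that absolute amplitudes stay
comparable across recordings — downstream amplitude thresholds (envelope
means in the denoiser, ternary thresholds in the pattern descriptor) depend
on a common scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

VALID_LABELS = ("normal", "ASD", "VSD", "abnormal")

# full-scale divisor per integer WAV dtype; scipy stores 24-bit PCM in the
# upper bytes of an int32, so int32's divisor covers it too
_FULL_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


@dataclass
class PcgRecording:
    """One heart-sound recording: samples in [-1, 1], rate in Hz, optional label."""

    samples: np.ndarray
    fs: float
    label: str | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def read_wav(path: str | Path, channel_mode: str = "reject") -> PcgRecording:
    """Read a PCM or float WAV file into a normalized :class:`PcgRecording`.

    Integer samples are divided by the full-scale magnitude of their bit
    depth (e.g. 16-bit by 32768); float samples are taken as-is.  Files with
    more than one channel are rejected unless ``channel_mode="mean"``, which
    averages channels (single-point auscultation produces mono audio, so
    multi-channel input usually signals a mistake).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such WAV file: {path}")
    fs, data = wavfile.read(str(path))
    if data.size == 0:
        raise ValueError(f"zero-length audio stream: {path}")

    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _FULL_SCALE:
        samples = data.astype(np.float64) / _FULL_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype} in {path}")

    if samples.ndim == 2:
        if channel_mode == "mean":
            samples = samples.mean(axis=1)
        elif channel_mode == "reject":
            raise ValueError(
                f"{path} has {samples.shape[1]} channels; expected mono "
                "(pass channel_mode='mean' to average)"
            )
        else:
            raise ValueError(f"unknown channel_mode {channel_mode!r}")
    return PcgRecording(samples=samples, fs=float(fs), source_id=path.stem)


def write_wav(rec: PcgRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM mono WAV, quantizing by rounding.

    Samples must already lie in [-1, 1]; +1.0 maps to the peak positive
    code 32767 (so a write/read round trip errs by at most 2**-15).
    """
    x = np.asarray(rec.samples, dtype=np.float64)
    if x.size and np.max(np.abs(x)) > 1.0 + 1e-12:
        raise ValueError("samples must lie in [-1, 1] before writing")
    codes = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(round(rec.fs)), codes)


def resample(rec: PcgRecording, fs_out: float, max_denominator: int = 1000) -> PcgRecording:
    """Polyphase resampling to ``fs_out`` Hz (explicit utility; reads never resample)."""
    if fs_out <= 0:
        raise ValueError("target rate must be positive")
    if fs_out == rec.fs:
        return PcgRecording(rec.samples.copy(), rec.fs, rec.label, rec.source_id)
    ratio = Fraction(fs_out / rec.fs).limit_denominator(max_denominator)
    y = resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    peak = np.max(np.abs(y)) if y.size else 0.0
    if peak > 1.0:  # polyphase ringing can overshoot full scale slightly
        y = y / peak
    return PcgRecording(y, fs_out, rec.label, rec.source_id)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load a dataset manifest CSV with columns ``path`` and ``label``."""
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    bad = set(df["label"]) - set(VALID_LABELS)
    if bad:
        warnings.warn(f"manifest contains unknown labels: {sorted(bad)}")
    return df


def write_manifest(rows: list[dict] | pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame(rows, columns=["path", "label"]).to_csv(path, index=False)
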