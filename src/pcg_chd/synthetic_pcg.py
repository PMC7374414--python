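"""Synthetic phonocardiogram generator for the three diagnostic classes.

Each recording is a train of cardiac cycles at a jittered heart rate.  A
cycle places the first heart sound S1 (valve closure "lub") at its start
and the second sound S2 ("dub") at ~35% of the cycle, both rendered as
Gaussian-enveloped sinusoids in the low heart-sound band.  The class then
shapes the systolic interval between them:

* ``normal`` — S1 and S2 only.
* ``VSD`` (ventricular septal defect) — a harsh *holosystolic* murmur:
  band-limited noise with a flat envelope spanning the whole S1->S2
  interval, as blood jets through the ventricular septum for all of
  systole.
* ``ASD`` (atrial septal defect) — a softer *mid-systolic*
  crescendo-decrescendo flow murmur, plus the auscultatory hallmark of a
  fixed split S2: the aortic (A2) and pulmonic (P2) components rendered as
  two sub-bursts separated by ``split_s2_ms``.

White noise is added at a configurable SNR and the result peak-normalized
to 0.9.  The murmur acoustics are stylized (filtered-noise bursts, not a
hemodynamic simulation) but sit inside the 20-200 Hz heart-sound band, so
the denoiser's IMF-rejection rule treats them like real murmurs.

Generation is deterministic given the seed; datasets derive one child seed
per recording from (seed, index), so the content of recording i does not
depend on how many recordings precede it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .signal_io import PcgRecording, write_wav

LABELS = ("normal", "ASD", "VSD")


@dataclass
class SynthParams:
    fs: float = 44100.0
    duration_s: float = 5.0
    heart_rate_bpm: float = 75.0
    heart_rate_jitter_bpm: float = 5.0
    # (center frequency Hz, duration ms, relative amplitude)
    s1_freq_hz: float = 40.0
    s1_dur_ms: float = 120.0
    s1_amp: float = 1.0
    s2_freq_hz: float = 60.0
    s2_dur_ms: float = 100.0
    s2_amp: float = 0.8
    # class-specific murmurs: band edges in Hz and amplitude relative to S1
    vsd_murmur_band_hz: tuple[float, float] = (80.0, 180.0)
    vsd_murmur_amp: float = 0.5
    asd_murmur_band_hz: tuple[float, float] = (60.0, 120.0)
    asd_murmur_amp: float = 0.35
    split_s2_ms: float = 50.0  # A2-P2 separation for the ASD fixed split
    snr_db: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration must be positive")
        if not 30.0 <= self.heart_rate_bpm <= 200.0:
            raise ValueError("heart rate must lie in [30, 200] bpm")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def _burst(t_axis: np.ndarray, center_s: float, freq: float, dur_ms: float,
           amp: float, phase: float) -> np.ndarray:
    """Gaussian-enveloped sinusoid burst centered at ``center_s`` seconds."""
    sigma = dur_ms / 1000.0 / 6.0  # +-3 sigma spans the nominal duration
    env = np.exp(-0.5 * ((t_axis - center_s) / sigma) ** 2)
    return amp * env * np.sin(2 * np.pi * freq * (t_axis - center_s) + phase)


def synth_recording(label: str, params: SynthParams | None = None) -> PcgRecording:
    """Generate one labeled 5-second recording (deterministic given the seed)."""
    p = params or SynthParams()
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(p.seed)
    n = int(round(p.fs * p.duration_s))
    t = np.arange(n) / p.fs
    clean = np.zeros(n)
    murmur_env = np.zeros(n)

    t_cycle = 0.0
    while t_cycle < p.duration_s:
        hr = p.heart_rate_bpm + rng.uniform(-p.heart_rate_jitter_bpm, p.heart_rate_jitter_bpm)
        period = 60.0 / hr
        s1_c = t_cycle + p.s1_dur_ms / 2000.0
        s2_c = t_cycle + 0.35 * period
        clean += _burst(t, s1_c, p.s1_freq_hz, p.s1_dur_ms, p.s1_amp, rng.uniform(0, 2 * np.pi))
        if label == "ASD":
            # fixed split S2: A2 then P2, each slightly attenuated
            for off in (0.0, p.split_s2_ms / 1000.0):
                clean += _burst(t, s2_c + off, p.s2_freq_hz, p.s2_dur_ms,
                                0.7 * p.s2_amp, rng.uniform(0, 2 * np.pi))
        else:
            clean += _burst(t, s2_c, p.s2_freq_hz, p.s2_dur_ms, p.s2_amp,
                            rng.uniform(0, 2 * np.pi))

        sys_start = s1_c + p.s1_dur_ms / 2000.0
        sys_end = s2_c - p.s2_dur_ms / 2000.0
        if sys_end > sys_start:
            in_systole = (t >= sys_start) & (t <= sys_end)
            if label == "VSD":
                murmur_env[in_systole] = 1.0  # flat, holosystolic
            elif label == "ASD":
                # crescendo-decrescendo (Hann) peaking mid-systole
                tau = (t[in_systole] - sys_start) / (sys_end - sys_start)
                murmur_env[in_systole] = np.sin(np.pi * tau) ** 2
        t_cycle += period

    if label in ("VSD", "ASD"):
        band = p.vsd_murmur_band_hz if label == "VSD" else p.asd_murmur_band_hz
        amp = p.vsd_murmur_amp if label == "VSD" else p.asd_murmur_amp
        sos = butter(4, band, btype="bandpass", fs=p.fs, output="sos")
        noise = sosfiltfilt(sos, rng.standard_normal(n))
        noise = noise / (np.sqrt(np.mean(noise**2)) + 1e-30)
        clean += amp * p.s1_amp * murmur_env * noise

    sig_power = float(np.mean(clean**2))
    noise_power = sig_power / 10.0 ** (p.snr_db / 10.0)
    out = clean + np.sqrt(noise_power) * rng.standard_normal(n)
    out *= 0.9 / np.max(np.abs(out))
    return PcgRecording(samples=out, fs=p.fs, label=label)


def make_dataset(
    n_per_class: int | dict[str, int],
    params: SynthParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[PcgRecording], pd.DataFrame]:
    """Generate a labeled dataset; optionally write WAVs plus a manifest CSV.

    ``n_per_class`` is either one count applied to every class or a mapping
    label -> count (e.g. ``{"normal": 140, "ASD": 85, "VSD": 55}``).  Each
    recording gets an independent child seed derived from ``(seed, index)``.
    """
    base = params or SynthParams()
    counts = {lab: n_per_class for lab in LABELS} if isinstance(n_per_class, int) else dict(n_per_class)
    for lab, cnt in counts.items():
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
        if cnt < 1:
            raise ValueError("counts must be >= 1")

    recordings: list[PcgRecording] = []
    rows: list[dict] = []
    index = 0
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for lab in LABELS:
        for j in range(counts.get(lab, 0)):
            child = int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))
            p_i = SynthParams(**{**base.__dict__, "seed": child})
            rec = synth_recording(lab, p_i)
            rec.source_id = f"{lab}_{j:04d}"
            recordings.append(rec)
            fname = f"{rec.source_id}.wav"
            rows.append({"path": fname, "label": lab})
            if out_path is not None:
                write_wav(rec, out_path / fname)
            index += 1
    manifest = pd.DataFrame(rows, columns=["path", "label"])
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return recordings, manifest
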