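"""Differential-MFCC feature extraction for birdsong recordings.

Pipeline (per clip): load mono 16 kHz audio -> optional denoise -> endpoint
detection (double threshold on short-time energy and zero-crossing rate) ->
13-d MFCC per 25 ms frame -> first- and second-order regression deltas ->
39-d fused frames -> non-overlapping stacks of 4 consecutive frames giving
one 156-d sample per stack.

The delta of a frame sequence C_0..C_{Q-1} with window K (default 2) is

    d_t = C_{t+1} - C_t                               t < K      (leading edge)
    d_t = sum_{k=1..K} k (C_{t+k} - C_{t-k})
          / sqrt(2 sum_{k=1..K} k^2)                  otherwise   (regression)
    d_t = C_t - C_{t-1}                               t >= Q - K  (trailing edge)

applied along the frame axis, one column of coefficients at a time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import dct, rfft
from scipy.io import wavfile

from .elm import FeatureTable

__all__ = [
    "AudioClip",
    "MfccConfig",
    "load_audio",
    "endpoint_detect",
    "mfcc_frames",
    "delta",
    "fuse_and_stack",
    "extract_clip",
    "extract_directory",
    "mel_filterbank",
]

TARGET_RATE = 16_000


@dataclass
class AudioClip:
    """Mono audio at 16 kHz with an optional species label."""

    samples: np.ndarray
    rate: int = TARGET_RATE
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("clip must be mono (1-d samples)")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class MfccConfig:
    frame_ms: float = 25.0
    hop_ms: float = 10.0
    n_mels: int = 26
    n_coeffs: int = 13
    delta_K: int = 2
    stack: int = 4
    preemphasis: float = 0.97
    fmin: float = 0.0
    fmax: float | None = None  # None -> Nyquist
    delta_axis: str = "frames"  # or "coeffs"

    def __post_init__(self) -> None:
        if self.delta_K not in (1, 2):
            raise ValueError("delta window K must be 1 or 2")
        if self.stack < 1:
            raise ValueError("stack must be >= 1")

    def frame_len(self, rate: int = TARGET_RATE) -> int:
        return int(round(self.frame_ms * rate / 1000))

    def hop_len(self, rate: int = TARGET_RATE) -> int:
        return int(round(self.hop_ms * rate / 1000))

    @property
    def sample_dim(self) -> int:
        return 3 * self.n_coeffs * self.stack

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.__dict__))


def load_audio(path: str | Path, label: str | None = None) -> AudioClip:
    """Read a PCM WAV file, average to mono and resample to 16 kHz."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError(f"{path}: empty audio file")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.abs(np.iinfo(data.dtype).min))
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if rate != TARGET_RATE:
        g = math.gcd(rate, TARGET_RATE)
        data = signal.resample_poly(data, TARGET_RATE // g, rate // g)
    return AudioClip(data, TARGET_RATE, label)


def endpoint_detect(
    clip: AudioClip,
    cfg: MfccConfig | None = None,
    energy_factor: float = 0.1,
    zcr_factor: float = 1.0,
) -> list[tuple[int, int]]:
    """Locate voiced segments by the classical double-threshold rule.

    The high threshold admits frames whose short-time energy exceeds
    ``energy_factor`` times the maximum frame energy; the low threshold
    (a quarter of the high one) admits quieter frames only when their
    zero-crossing rate also exceeds ``zcr_factor`` times the mean ZCR,
    which picks up noisy syllable edges without admitting the noise floor.
    Setting both factors to 0 accepts every frame.  Returns (start, end)
    sample index pairs; an all-silent clip yields an empty list.
    """
    cfg = cfg or MfccConfig()
    frame, hop = cfg.frame_len(clip.rate), cfg.hop_len(clip.rate)
    x = clip.samples
    if x.size < frame:
        return []
    frames = _frame_signal(x, frame, hop)
    energy = np.sum(frames**2, axis=1)
    zcr = np.mean(np.abs(np.diff(np.signbit(frames), axis=1)), axis=1)
    if energy.max() == 0:
        return []
    high = energy >= energy_factor * energy.max()
    low = (energy >= 0.25 * energy_factor * energy.max()) & (
        zcr >= zcr_factor * zcr.mean()
    )
    voiced = high | low
    segments: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(voiced):
        if v and start is None:
            start = i
        elif not v and start is not None:
            segments.append((start * hop, (i - 1) * hop + frame))
            start = None
    if start is not None:
        segments.append((start * hop, (len(voiced) - 1) * hop + frame))
    return segments


def _frame_signal(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    n_frames = (x.size - frame) // hop + 1
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def mel_filterbank(
    n_mels: int, n_fft: int, rate: int, fmin: float = 0.0, fmax: float | None = None
) -> np.ndarray:
    """Triangular mel filters (n_mels x (n_fft//2 + 1)), unit peak height."""
    fmax = fmax or rate / 2

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / rate).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for m in range(1, n_mels + 1):
        lo, ctr, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, ctr):
            if ctr > lo:
                fb[m - 1, k] = (k - lo) / (ctr - lo)
        for k in range(ctr, hi):
            if hi > ctr:
                fb[m - 1, k] = (hi - k) / (hi - ctr)
    return fb


def mfcc_frames(clip: AudioClip, cfg: MfccConfig | None = None) -> np.ndarray:
    """13-d MFCC matrix (frames x n_coeffs): pre-emphasis, Hamming-windowed
    framing, FFT magnitude, mel filterbank, log, DCT-II; c0 is dropped and
    coefficients 1..13 kept."""
    cfg = cfg or MfccConfig()
    frame, hop = cfg.frame_len(clip.rate), cfg.hop_len(clip.rate)
    x = clip.samples
    if x.size < frame:
        raise ValueError(
            f"clip of {x.size} samples is shorter than one {frame}-sample frame"
        )
    x = np.concatenate([[x[0]], x[1:] - cfg.preemphasis * x[:-1]])
    frames = _frame_signal(x, frame, hop) * np.hamming(frame)
    n_fft = int(2 ** np.ceil(np.log2(frame)))
    mag = np.abs(rfft(frames, n=n_fft, axis=1))
    fb = mel_filterbank(cfg.n_mels, n_fft, clip.rate, cfg.fmin, cfg.fmax)
    mel_energy = mag @ fb.T
    log_mel = np.log(np.maximum(mel_energy, 1e-10))
    cepstra = dct(log_mel, type=2, norm="ortho", axis=1)
    return cepstra[:, 1 : cfg.n_coeffs + 1]


def delta(coeffs: np.ndarray, K: int = 2) -> np.ndarray:
    """Regression difference along the frame axis (rows), edge frames by
    simple forward/backward differences; see the module docstring."""
    C = np.asarray(coeffs, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    Q = C.shape[0]
    if Q < 2:
        raise ValueError("need at least 2 frames to difference")
    d = np.zeros_like(C)
    denom = math.sqrt(2 * sum(k * k for k in range(1, K + 1)))
    for t in range(Q):
        if t < K:
            d[t] = C[t + 1] - C[t]
        elif t >= Q - K:
            d[t] = C[t] - C[t - 1]
        else:
            d[t] = sum(k * (C[t + k] - C[t - k]) for k in range(1, K + 1)) / denom
    return d if coeffs.ndim > 1 else d[:, 0]


def fuse_and_stack(mfcc: np.ndarray, cfg: MfccConfig | None = None) -> np.ndarray:
    """Concatenate [MFCC, delta, delta-delta] per frame (39-d) and group each
    consecutive non-overlapping `stack` frames into one sample (156-d at the
    defaults); a trailing remainder shorter than `stack` is dropped."""
    cfg = cfg or MfccConfig()
    mfcc = np.atleast_2d(np.asarray(mfcc, dtype=float))
    if mfcc.shape[0] < 2:
        return np.empty((0, cfg.sample_dim))
    d1 = delta(mfcc, cfg.delta_K)
    d2 = delta(d1, cfg.delta_K)
    fused = np.hstack([mfcc, d1, d2])  # frames x 39
    n_samples = fused.shape[0] // cfg.stack
    if n_samples == 0:
        return np.empty((0, cfg.sample_dim))
    return fused[: n_samples * cfg.stack].reshape(n_samples, -1)


def extract_clip(clip: AudioClip, cfg: MfccConfig | None = None) -> np.ndarray:
    """Full per-clip pipeline: endpoint detection, MFCC, fuse and stack.
    Returns a (samples x 156) matrix; empty when nothing voiced or too short."""
    cfg = cfg or MfccConfig()
    segments = endpoint_detect(clip, cfg)
    if not segments:
        return np.empty((0, cfg.sample_dim))
    voiced = np.concatenate([clip.samples[a:b] for a, b in segments])
    if voiced.size < cfg.frame_len(clip.rate):
        return np.empty((0, cfg.sample_dim))
    return fuse_and_stack(mfcc_frames(AudioClip(voiced, clip.rate), cfg), cfg)


def extract_directory(
    root: str | Path,
    cfg: MfccConfig | None = None,
    manifest: str | Path | None = None,
) -> FeatureTable:
    """Build a labeled FeatureTable from WAVs.

    Labels come either from a ``manifest`` CSV (columns filename,label) or
    from the directory layout ``<root>/<species>/<file>.wav``.  Species are
    assigned 1-based integer labels in sorted name order.
    """
    cfg = cfg or MfccConfig()
    root = Path(root)
    pairs: list[tuple[Path, str]] = []
    if manifest is not None:
        df = pd.read_csv(manifest)
        pairs = [(root / f, str(lab)) for f, lab in zip(df["filename"], df["label"])]
    else:
        for wav in sorted(root.glob("*/*.wav")):
            pairs.append((wav, wav.parent.name))
    if not pairs:
        raise FileNotFoundError(f"no labeled WAV files under {root}")
    names = sorted({lab for _, lab in pairs})
    label_of = {name: i + 1 for i, name in enumerate(names)}
    X_parts, y_parts = [], []
    for wav, lab in pairs:
        feats = extract_clip(load_audio(wav), cfg)
        if feats.shape[0]:
            X_parts.append(feats)
            y_parts.append(np.full(feats.shape[0], label_of[lab]))
    if not X_parts:
        raise ValueError(f"no voiced audio found under {root}")
    return FeatureTable(np.vstack(X_parts), np.concatenate(y_parts), names)
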