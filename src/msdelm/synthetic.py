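"""Synthetic desk-scale test data with the structure the classifier assumes.

Two generators:

* :func:`gen_clusters` — multi-class Gaussian feature clusters of
  configurable dimension and separation, standing in for an extracted
  feature table.  Class c's mean sits at separation `s` along its own unit
  direction (orthogonal axes while c <= df, random unit directions beyond),
  with isotropic unit within-class variance, so `s` is the mean-to-origin
  distance in within-class standard deviations.
* :func:`gen_songs` — short tonal "songs": amplitude-modulated harmonic
  stacks at species-specific fundamentals plus white noise at a target SNR,
  written as 16 kHz mono WAVs with a filename,label manifest.  These exercise
  the audio pipeline end to end without any recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .elm import FeatureTable

__all__ = ["ClusterSpec", "SongSpec", "gen_clusters", "gen_songs"]


@dataclass
class ClusterSpec:
    n_classes: int = 5
    samples_per_class: int = 100
    df: int = 20
    separation: float = 3.0
    heavy_tails: bool = False  # Student-t(3) noise instead of Gaussian
    imbalance: float = 1.0  # ratio largest/smallest class size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.df < 1 or self.samples_per_class < 1:
            raise ValueError("df and samples_per_class must be positive")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")


@dataclass
class SongSpec:
    n_species: int = 3
    fundamentals: tuple[float, ...] = (800.0, 1600.0, 2400.0)
    harmonic_weights: tuple[float, ...] = (1.0, 0.5, 0.25)
    syllable_rate: float = 4.0  # Hz, amplitude-modulation rate
    duration: float = 1.0  # seconds per clip
    snr_db: float | None = 30.0  # None -> noise-free
    clips_per_species: int = 5
    rate: int = 16_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration < 0.5:
            raise ValueError("clips must be at least 0.5 s")
        if len(self.fundamentals) < self.n_species:
            raise ValueError("need one fundamental per species")
        if len(set(self.fundamentals[: self.n_species])) != self.n_species:
            raise ValueError("species fundamentals must be distinct")


def gen_clusters(spec: ClusterSpec) -> FeatureTable:
    """Labeled Gaussian clusters; exactly the specified rows per class (the
    imbalance option scales class sizes geometrically between 1x and the
    given ratio)."""
    rng = np.random.default_rng(spec.seed)
    P, df, s = spec.n_classes, spec.df, spec.separation
    if spec.imbalance == 1.0:
        sizes = np.full(P, spec.samples_per_class)
    else:
        factors = np.geomspace(1.0, spec.imbalance, P)
        sizes = np.maximum(1, np.round(spec.samples_per_class * factors)).astype(int)
    means = np.zeros((P, df))
    for c in range(P):
        if c < df:
            means[c, c] = s
        else:
            u = rng.normal(size=df)
            means[c] = s * u / np.linalg.norm(u)
    X_parts, y_parts = [], []
    for c in range(P):
        if spec.heavy_tails:
            noise = rng.standard_t(3, size=(sizes[c], df))
        else:
            noise = rng.normal(size=(sizes[c], df))
        X_parts.append(means[c] + noise)
        y_parts.append(np.full(sizes[c], c + 1))
    return FeatureTable(np.vstack(X_parts), np.concatenate(y_parts))


def _song_waveform(
    spec: SongSpec, species: int, rng: np.random.Generator
) -> np.ndarray:
    n = int(spec.duration * spec.rate)
    t = np.arange(n) / spec.rate
    f0 = spec.fundamentals[species]
    tone = np.zeros(n)
    for h, w in enumerate(spec.harmonic_weights, start=1):
        # small random phase so clips of one species are not byte-identical
        tone += w * np.sin(2 * np.pi * h * f0 * t + rng.uniform(0, 2 * np.pi))
    # syllable envelope: raised cosine at the syllable rate
    envelope = 0.5 * (1 - np.cos(2 * np.pi * spec.syllable_rate * t))
    x = tone * envelope
    if spec.snr_db is not None and np.isfinite(spec.snr_db):
        p_signal = np.mean(x**2)
        p_noise = p_signal / (10 ** (spec.snr_db / 10))
        x = x + rng.normal(scale=np.sqrt(p_noise), size=n)
    return x / np.max(np.abs(x))


def gen_songs(spec: SongSpec, outdir: str | Path) -> pd.DataFrame:
    """Write WAV clips and a manifest CSV (filename,label) under `outdir`;
    returns the manifest frame.  Species are named species_1..species_n."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for sp in range(spec.n_species):
        label = f"species_{sp + 1}"
        for c in range(spec.clips_per_species):
            x = _song_waveform(spec, sp, rng)
            fname = f"{label}_clip{c:02d}.wav"
            wavfile.write(out / fname, spec.rate, (x * 32767).astype(np.int16))
            rows.append({"filename": fname, "label": label})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
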