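"""Classic timbre descriptors and perceptual-space utilities.

Log attack time (the -40 dB to -12 dB rise of the amplitude envelope),
spectral centroid of the compressed auditory filterbank profile (exponent
0.3), and non-metric multidimensional scaling of dissimilarity matrices
with Kruskal stress-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert
from sklearn.manifold import MDS

from .periphery import LOW_FREQ, N_CHANNELS, N_OCTAVES, auditory_spectrogram, spectral_profile
from .similarity import DissimilarityMatrix
from .synth import Waveform

ATTACK_LOW_DB = -40.0
ATTACK_HIGH_DB = -12.0
CENTROID_EXPONENT = 0.3


@dataclass
class DescriptorRow:
    instrument: str
    log_attack_time: float
    spectral_centroid: float  # channel-index units
    spectral_centroid_hz: float


def _envelope(x: np.ndarray, fs: float, smooth_s: float = 0.010) -> np.ndarray:
    env = np.abs(hilbert(x))
    n = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(n) / n
    return np.convolve(env, kernel, mode="same")


def _first_crossing(env: np.ndarray, level: float, fs: float) -> float:
    """Time of the first upward crossing of ``level``, linearly interpolated."""
    above = env >= level
    if above[0]:
        return 0.0
    idx = int(np.argmax(above))
    if not above[idx]:
        raise ValueError("envelope never reaches the threshold")
    e0, e1 = env[idx - 1], env[idx]
    frac = (level - e0) / (e1 - e0) if e1 > e0 else 0.0
    return (idx - 1 + frac) / fs


def attack_time(w: Waveform) -> float:
    """log10 of the time taken to rise from -40 dB to -12 dB relative to the
    maximum envelope amplitude (clamped to one sample period).

    The -12 dB point is the first upward crossing; the -40 dB point is the
    last sub-threshold instant before it, which keeps the measurement on
    the rise segment itself and away from analytic-signal leakage into any
    leading silence.
    """
    x = w.samples
    if not np.any(x):
        raise ValueError("silent waveform has no attack")
    fs = w.sample_rate
    env = _envelope(x, fs)
    peak = env.max()
    hi = peak * 10 ** (ATTACK_HIGH_DB / 20)
    lo = peak * 10 ** (ATTACK_LOW_DB / 20)
    t_high = _first_crossing(env, hi, fs)
    i_high = int(np.floor(t_high * fs)) + 1
    below = np.where(env[:i_high] <= lo)[0]
    if below.size == 0:
        t_low = 0.0
    else:
        i = int(below[-1])
        e0, e1 = env[i], env[min(i + 1, env.size - 1)]
        frac = (lo - e0) / (e1 - e0) if e1 > e0 else 0.0
        t_low = (i + frac) / fs
    dt = max(t_high - t_low, 1.0 / fs)
    return float(np.log10(dt))


def channel_to_hz(channel: float) -> float:
    """Convert a (possibly fractional) channel index to Hz on the CF grid."""
    return LOW_FREQ * 2.0 ** (channel * N_OCTAVES / (N_CHANNELS - 1))


def spectral_centroid(w: Waveform) -> float:
    """Center of mass (channel units) of the compressed auditory profile."""
    if not np.any(w.samples):
        raise ValueError("silent waveform has no spectral centroid")
    profile = spectral_profile(auditory_spectrogram(w))
    compressed = (profile**2) ** CENTROID_EXPONENT  # channel energy, exponent 0.3
    total = compressed.sum()
    if total == 0:
        raise ValueError("empty spectral profile")
    return float(np.dot(np.arange(N_CHANNELS), compressed) / total)


def descriptor_table(waveforms, instruments) -> pd.DataFrame:
    rows = []
    for w, name in zip(waveforms, instruments):
        c = spectral_centroid(w)
        rows.append(
            DescriptorRow(name, attack_time(w), c, channel_to_hz(c)).__dict__
        )
    return pd.DataFrame(rows)


def nonmetric_mds(
    d: DissimilarityMatrix, dims: int = 2, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Standard non-metric MDS; returns (configuration, Kruskal stress-1)."""
    v = d.values
    if not np.allclose(v, v.T, atol=1e-9):
        raise ValueError("dissimilarity matrix must be symmetric")
    mds = MDS(
        n_components=dims,
        metric=False,
        dissimilarity="precomputed",
        normalized_stress=True,
        n_init=8,
        max_iter=500,
        random_state=seed % (2**32),
    )
    coords = mds.fit_transform(v)
    return coords, float(mds.stress_)
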