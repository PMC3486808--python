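"""Synthetic instrument notes, ripple probes, stimuli and simulated observers.

Stands in for the recorded note databases, physiological probe stimuli and
human rating sessions that the modelling pipeline otherwise consumes.  Notes
are built by additive synthesis: harmonics of a fundamental with a per-class
spectral envelope, a common attack/decay amplitude envelope, sinusoidal
frequency vibrato and amplitude shimmer.  Eleven instrument archetypes in
three classes (strings, winds, percussions) provide the benchmark dataset,
each spanning a range of pitches, playing styles and dynamics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .similarity import DissimilarityMatrix

logger = logging.getLogger(__name__)

TARGET_FS = 16000
#: stimulus truncation length and offset ramp (s)
STIMULUS_DURATION = 0.25
OFFSET_RAMP = 0.05
#: digital RMS reference for stimulus normalization (the presentation level
#: in the booth is acoustic; any fixed digital reference serves the model)
RMS_REFERENCE = 0.05


@dataclass
class Waveform:
    """A monaural waveform: dimensionless samples at a given rate."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass
class NoteParams:
    """Generative parameters of one synthetic note."""

    f0: float
    n_harmonics: int = 20
    spectral_envelope: str = "smooth-decay"  # or "resonant-peaks"
    decay_slope_db_oct: float = -6.0
    resonance_centers_oct: tuple = ()
    resonance_width_oct: float = 0.5
    resonance_gain_db: float = 12.0
    even_harmonic_atten_db: float = 0.0
    attack: float = 0.03
    decay: float = 0.3
    sustain_level: float = 0.7
    vibrato_rate: float = 0.0
    vibrato_depth: float = 0.0
    shimmer_rate: float = 5.0
    shimmer_depth: float = 0.0
    partial_jitter: float = 0.0
    duration: float = 0.5
    amplitude: float = 1.0
    class_label: str = "string"
    instrument: str = "generic"
    style: str = "normal"
    dynamic: str = "mezzo"

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not 0.0 <= self.sustain_level <= 1.0:
            raise ValueError("sustain_level must lie in [0, 1]")
        if self.attack < 0 or self.decay < 0:
            raise ValueError("attack and decay must be non-negative")
        if self.vibrato_depth < 0:
            raise ValueError("vibrato_depth must be non-negative")


def synth_note(params: NoteParams, seed: int, sample_rate: int = TARGET_FS) -> Waveform:
    """Additive synthesis of one note; bit-reproducible for fixed (params, seed)."""
    rng = np.random.default_rng(seed)
    n = int(round(params.duration * sample_rate))
    t = np.arange(n) / sample_rate

    nyq = sample_rate / 2.0
    k = np.arange(1, params.n_harmonics + 1)
    jitter = (
        rng.normal(0.0, params.partial_jitter, size=k.size)
        if params.partial_jitter > 0
        else np.zeros(k.size)
    )
    freqs = k * params.f0 * (1.0 + jitter)
    keep = freqs < nyq * (1.0 - 1e-6)
    if not np.all(keep):
        logger.warning(
            "harmonics above Nyquist truncated: kept %d of %d", keep.sum(), k.size
        )
    k, freqs = k[keep], freqs[keep]

    gains_db = params.decay_slope_db_oct * np.log2(k)
    if params.spectral_envelope == "resonant-peaks" and params.resonance_centers_oct:
        pos = np.log2(k)  # harmonic position in octaves above f0
        for c in params.resonance_centers_oct:
            gains_db = gains_db + params.resonance_gain_db * np.exp(
                -0.5 * ((pos - c) / params.resonance_width_oct) ** 2
            )
    gains_db = gains_db - np.where(k % 2 == 0, params.even_harmonic_atten_db, 0.0)
    gains = 10.0 ** (gains_db / 20.0)

    # common amplitude envelope: linear attack, exponential decay to sustain
    env = np.ones(n)
    na = int(round(params.attack * sample_rate))
    if na > 0:
        ramp = np.arange(min(na, n)) / na
        env[: ramp.size] = ramp
    if params.decay > 0:
        td = np.maximum(t - params.attack, 0.0)
        env = env * (
            params.sustain_level
            + (1.0 - params.sustain_level) * np.exp(-td / params.decay)
        )

    # sinusoidal frequency vibrato: phase integrates f_k(t) = k f0 (1 + d sin)
    phases = rng.uniform(0, 2 * np.pi, size=k.size)
    if params.vibrato_rate > 0 and params.vibrato_depth > 0:
        wobble = -(params.vibrato_depth / (2 * np.pi * params.vibrato_rate)) * np.cos(
            2 * np.pi * params.vibrato_rate * t
        )
        wobble = wobble - wobble[0]
    else:
        wobble = 0.0
    arg = 2 * np.pi * freqs[:, None] * (t[None, :] + wobble)
    x = (gains[:, None] * np.sin(arg + phases[:, None])).sum(axis=0)

    if params.shimmer_depth > 0 and params.shimmer_rate > 0:
        x = x * (
            1.0
            + params.shimmer_depth * np.sin(2 * np.pi * params.shimmer_rate * t)
        )
    x = x * env
    peak = np.max(np.abs(x))
    if peak > 0:
        x = params.amplitude * x / peak
    return Waveform(x, sample_rate)


def synth_ripple(
    rate_hz: float,
    scale_cpo: float,
    direction: str = "down",
    duration: float = 1.0,
    sample_rate: int = TARGET_FS,
    depth: float = 0.9,
    carriers_per_octave: int = 24,
    low_freq: float = 180.0,
    n_octaves: float = 5.3,
    seed: int = 12345,
) -> Waveform:
    """Broadband moving ripple: log-spaced carriers with a drifting sinusoidal
    spectro-temporal envelope of the requested density and velocity.

    A downward ripple's spectral peaks drift toward low frequencies over
    time (envelope phase ``rate*t + scale*x``); upward is the mirror image.
    """
    if rate_hz < 0 or scale_cpo < 0:
        raise ValueError("rate and scale must be non-negative")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    x_oct = np.arange(0.0, n_octaves, 1.0 / carriers_per_octave)
    freqs = low_freq * 2.0**x_oct
    freqs = freqs[freqs < sample_rate / 2.0]
    x_oct = x_oct[: freqs.size]
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    sgn = 1.0 if direction == "down" else -1.0
    out = np.zeros(n)
    for f, xo, ph in zip(freqs, x_oct, phases):
        env = 1.0 + depth * np.cos(2 * np.pi * (sgn * rate_hz * t + scale_cpo * xo))
        out += env * np.sin(2 * np.pi * f * t + ph)
    out /= np.max(np.abs(out))
    return Waveform(out, sample_rate)


def make_stimulus(w: Waveform, rms_reference: float = RMS_REFERENCE) -> Waveform:
    """Truncate to 250 ms, apply a 50-ms raised-cosine offset ramp (onset
    preserved), and normalize RMS power to the configured reference."""
    n_keep = int(round(STIMULUS_DURATION * w.sample_rate))
    if w.samples.size < n_keep:
        raise ValueError("input shorter than the 250-ms stimulus duration")
    x = w.samples[:n_keep].copy()
    n_ramp = int(round(OFFSET_RAMP * w.sample_rate))
    ramp = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, n_ramp + 1) / n_ramp))
    x[-n_ramp:] *= ramp
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("silent input cannot be RMS-normalized")
    return Waveform(x * (rms_reference / rms), w.sample_rate)


def preprocess(w: Waveform) -> Waveform:
    """Resample to 16 kHz and apply the pre-emphasis FIR [1, -0.97]."""
    x = w.samples
    fs = w.sample_rate
    if fs != TARGET_FS:
        frac = Fraction(TARGET_FS, int(round(fs))).limit_denominator(10000)
        y = resample_poly(x, frac.numerator, frac.denominator)
        n_target = int(round(x.size * TARGET_FS / fs))
        if y.size > n_target:
            y = y[:n_target]
        elif y.size < n_target:
            y = np.pad(y, (0, n_target - y.size))
        x = y
    x = np.concatenate([[x[0]], x[1:] - 0.97 * x[:-1]]) if x.size else x
    return Waveform(x, TARGET_FS)


def trial_design(n_sounds: int, seed: int) -> list[tuple[int, int]]:
    """All n(n-1) ordered pairs of distinct sounds, shuffled by seed."""
    if n_sounds < 2:
        raise ValueError("need at least 2 sounds")
    pairs = [(i, j) for i in range(n_sounds) for j in range(n_sounds) if i != j]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


@dataclass
class ObserverRatings:
    """One simulated rating session: per-order matrix and its symmetric average."""

    ordered: np.ndarray  # full n x n, (i, j) = rating when i played first
    averaged: DissimilarityMatrix


def simulate_observer(
    true_d: DissimilarityMatrix, noise_sd: float, seed: int
) -> ObserverRatings:
    """Slider ratings: monotone [0, 1] rescaling of the true parameter
    distances plus Gaussian rating noise, clipped to the slider range."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    v = true_d.values
    n = true_d.n
    off = v[~np.eye(n, dtype=bool)]
    lo, hi = off.min(), off.max()
    scaled = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    noise = rng.normal(0.0, noise_sd, size=v.shape) if noise_sd > 0 else 0.0
    ordered = np.clip(scaled + noise, 0.0, 1.0)
    np.fill_diagonal(ordered, 0.0)
    avg = 0.5 * (ordered + ordered.T)
    np.fill_diagonal(avg, 0.0)
    return ObserverRatings(ordered, DissimilarityMatrix(avg, list(true_d.names)))


# ---------------------------------------------------------------------------
# instrument archetypes and the benchmark dataset

#: Eleven archetypes in three classes, built to differ *temporally*: every
#: instrument shares the same register, harmonic count and mean spectral
#: slope, and body resonances are redrawn per note, so sustained spectral
#: shape underdetermines identity.  What distinguishes instruments is the
#: temporal envelope (attack, decay, sustain) and its modulations (vibrato
#: rate/depth for strings, breath shimmer rate/depth for winds, tremolo and
#: inharmonic jitter for percussion).
INSTRUMENTS: dict[str, NoteParams] = {
    "violin": NoteParams(
        f0=220.0, class_label="string", instrument="violin",
        attack=0.12, decay=1.0, sustain_level=0.85,
        vibrato_rate=6.0, vibrato_depth=0.010,
    ),
    "cello": NoteParams(
        f0=220.0, class_label="string", instrument="cello",
        attack=0.16, decay=1.0, sustain_level=0.85,
        vibrato_rate=6.3, vibrato_depth=0.006,
    ),
    "piano": NoteParams(
        f0=220.0, class_label="string", instrument="piano",
        attack=0.008, decay=0.35, sustain_level=0.0, partial_jitter=0.002,
    ),
    "vibraphone": NoteParams(
        f0=220.0, class_label="percussion", instrument="vibraphone",
        attack=0.004, decay=0.5, sustain_level=0.0, partial_jitter=0.02,
        shimmer_rate=5.0, shimmer_depth=0.3,
    ),
    "marimba": NoteParams(
        f0=220.0, class_label="percussion", instrument="marimba",
        attack=0.003, decay=0.15, sustain_level=0.0, partial_jitter=0.04,
    ),
    "oboe": NoteParams(
        f0=220.0, class_label="wind", instrument="oboe",
        attack=0.040, decay=1.0, sustain_level=0.9,
        vibrato_rate=5.0, vibrato_depth=0.003, shimmer_rate=4.5, shimmer_depth=0.06,
    ),
    "clarinet": NoteParams(
        f0=220.0, class_label="wind", instrument="clarinet",
        attack=0.050, decay=1.0, sustain_level=0.9,
        shimmer_rate=6.5, shimmer_depth=0.05,
    ),
    "saxophone": NoteParams(
        f0=220.0, class_label="wind", instrument="saxophone",
        attack=0.060, decay=1.0, sustain_level=0.9,
        vibrato_rate=5.5, vibrato_depth=0.004, shimmer_rate=5.0, shimmer_depth=0.12,
    ),
    "trumpet": NoteParams(
        f0=220.0, class_label="wind", instrument="trumpet",
        attack=0.030, decay=1.0, sustain_level=0.9,
        shimmer_rate=7.0, shimmer_depth=0.08,
    ),
    "trombone": NoteParams(
        f0=220.0, class_label="wind", instrument="trombone",
        attack=0.055, decay=1.0, sustain_level=0.9,
        shimmer_rate=3.5, shimmer_depth=0.09,
    ),
    "bassoon": NoteParams(
        f0=220.0, class_label="wind", instrument="bassoon",
        attack=0.050, decay=1.0, sustain_level=0.9,
        vibrato_rate=4.5, vibrato_depth=0.005, shimmer_rate=5.5, shimmer_depth=0.07,
    ),
}

STYLES = ("normal", "staccato", "espressivo")
DYNAMICS = ("piano", "mezzo", "forte")


@dataclass
class InstrumentDataset:
    """Synthetic benchmark: waveforms with labels, generative parameters and
    the ground-truth dissimilarity between instruments in parameter space."""

    waveforms: list[Waveform]
    labels: list[str]
    classes: list[str]
    params: list[NoteParams]
    true_dissimilarity: DissimilarityMatrix

    def __post_init__(self) -> None:
        if not (
            len(self.waveforms) == len(self.labels) == len(self.params) == len(self.classes)
        ):
            raise ValueError("dataset fields must have equal lengths")

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "instrument": self.labels,
                "class": self.classes,
                "f0": [p.f0 for p in self.params],
                "style": [p.style for p in self.params],
                "dynamic": [p.dynamic for p in self.params],
            }
        )


def _template_descriptor(p: NoteParams) -> np.ndarray:
    """Generative-parameter coordinates used for ground-truth dissimilarity."""
    res = np.mean(p.resonance_centers_oct) if p.resonance_centers_oct else 0.0
    return np.array(
        [
            np.log10(max(p.attack, 1e-4)),
            np.log10(max(p.decay, 1e-3)),
            p.decay_slope_db_oct,
            p.vibrato_depth * 100.0,
            p.vibrato_rate,
            p.shimmer_depth,
            p.shimmer_rate if p.shimmer_depth > 0 else 0.0,
            p.sustain_level,
            res,
        ]
    )


def true_instrument_dissimilarity(
    templates: dict[str, NoteParams] | None = None,
) -> DissimilarityMatrix:
    """Euclidean distance between instruments in the standardized
    generative-parameter space (log attack, envelope slope, vibrato depth,
    shimmer, sustain, resonance position)."""
    templates = templates or INSTRUMENTS
    names = sorted(templates)
    X = np.stack([_template_descriptor(templates[n]) for n in names])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    diff = Z[:, None, :] - Z[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return DissimilarityMatrix(d, names)


def _vary_note(base: NoteParams, rng: np.random.Generator) -> NoteParams:
    """One sampled note: pitch over ~1.3 octaves in the shared register,
    style and dynamic tags, mild jitter on the temporal parameters, and a
    freshly drawn spectral envelope (slope and body resonances) so that
    sustained spectral shape carries little instrument identity."""
    semitones = int(rng.integers(-8, 9))
    style = STYLES[rng.integers(len(STYLES))]
    dyn = DYNAMICS[rng.integers(len(DYNAMICS))]
    f0 = base.f0 * 2.0 ** (semitones / 12.0)
    g = lambda s: float(np.exp(rng.normal(0.0, s)))
    p = replace(
        base,
        f0=f0,
        attack=base.attack * g(0.15),
        decay=base.decay * g(0.15),
        vibrato_depth=base.vibrato_depth * g(0.1),
        shimmer_depth=base.shimmer_depth * g(0.1),
        spectral_envelope="resonant-peaks",
        decay_slope_db_oct=-6.0 + rng.normal(0.0, 1.0),
        resonance_centers_oct=tuple(np.sort(rng.uniform(0.5, 2.5, size=2))),
        resonance_width_oct=0.4,
        resonance_gain_db=10.0,
        style=style,
        dynamic=dyn,
        amplitude={"piano": 0.4, "mezzo": 0.7, "forte": 1.0}[dyn],
        duration=0.35,
    )
    if style == "staccato":
        p = replace(p, decay=min(p.decay, 0.08), sustain_level=0.0)
    elif style == "espressivo" and p.vibrato_rate > 0:
        p = replace(p, vibrato_depth=p.vibrato_depth * 1.5)
    return p


def make_dataset(
    notes_per_instrument: int = 100,
    seed: int = 0,
    templates: dict[str, NoteParams] | None = None,
) -> InstrumentDataset:
    """The default synthetic benchmark: 11 instruments x N notes."""
    templates = templates or INSTRUMENTS
    names = sorted(templates)
    rng = np.random.default_rng(seed)
    waveforms, labels, classes, params = [], [], [], []
    for name in names:
        base = templates[name]
        for _ in range(notes_per_instrument):
            p = _vary_note(base, rng)
            w = synth_note(p, seed=int(rng.integers(2**31)))
            waveforms.append(w)
            labels.append(name)
            classes.append(base.class_label)
            params.append(p)
    return InstrumentDataset(
        waveforms, labels, classes, params, true_instrument_dissimilarity(templates)
    )


# ---------------------------------------------------------------------------
# WAV / manifest I/O


def write_wav(path, w: Waveform) -> None:
    wavfile.write(path, int(w.sample_rate), w.samples.astype(np.float32))


def read_wav(path) -> Waveform:
    fs, x = wavfile.read(path)
    if x.ndim > 1:
        raise ValueError("only monaural audio is supported")
    if np.issubdtype(x.dtype, np.integer):
        x = x.astype(float) / float(np.iinfo(x.dtype).max)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        x = np.asarray(x, dtype=float)
    return Waveform(x, fs)
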