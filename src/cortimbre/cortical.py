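"""Cortical stage: spectro-temporal modulation analysis of the spectrogram.

The full model is a bank of directional modulation filters, one per
(rate, scale, direction) triple, applied at every tonotopic channel: an
affine wavelet transform of the auditory spectrogram with a mother wavelet
that is Gabor-shaped along frequency and exponentially damped along time.
Rates cover 4–128 Hz (11 values, each upward and downward), scales cover
0.25–8 cycles/octave (11 values); applied across 128 channels this spans a
30,976-filter space.  Only response magnitudes are kept, time-averaged over
the note, yielding a 128 x 22 x 11 tensor per note.

Control variants implemented alongside: the *separable* model (independent
1-D rate and scale filters, 4,224 dims), the *global* modulation profile
(rate and scale marginals, 33 dims), and the *undersampled* joint model
(64 channels x 10 rates x 6 scales = 3,840 dims).  Measured
spectro-temporal receptive fields (STRFs) can be applied in place of the
model filterbank after alignment to the 128-channel grid.

Convolution conventions
-----------------------
The joint transform convolves linearly (causally, zero-padded) along time
and circularly along the 128-channel tonotopic axis, where the Gabor kernel
is defined on the wrapped octave grid.  The separable transform instead
uses circular convolution on the note's own frame grid with transfer
functions that are exactly one-sided in the DFT domain; this makes its
features exactly invariant to modulation phase — and hence to ripple
direction — for probe ripples completing integer cycles over the note.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.interpolate import interp1d
from scipy.signal import hilbert

from .periphery import (
    CHANNEL_STEP_OCT,
    DEFAULT_FRAME_RATE,
    LOW_FREQ,
    N_CHANNELS,
    N_OCTAVES,
    AuditorySpectrogram,
    center_frequencies,
)

logger = logging.getLogger(__name__)

#: characteristic rates (Hz) and scales (cycles/octave) of the full model
RATES = (4.0, 5.7, 8.0, 11.3, 16.0, 22.6, 32.0, 45.3, 64.0, 90.5, 128.0)
SCALES = (0.25, 0.35, 0.50, 0.71, 1.00, 1.41, 2.00, 2.83, 4.00, 5.66, 8.00)
#: coarse lists of the undersampled control model
UNDERSAMPLED_RATES = (4.0, 8.0, 16.0, 32.0, 64.0)
UNDERSAMPLED_SCALES = (0.25, 0.47, 0.87, 1.62, 3.03, 5.67)

DIRECTIONS = ("up", "down")

# Kernel calibration: the raw temporal seed t^2 e^{-3.5 t} sin(2 pi t) peaks
# slightly below 1 Hz and the raw Ricker spectral seed (1-x^2) e^{-x^2/2}
# peaks at sqrt(2)/(2 pi) cycles per unit; both arguments are rescaled so a
# filter's peak modulation response sits exactly at its nominal rate/scale.
_SPECTRAL_CAL = 2.0 * np.pi / np.sqrt(2.0)
_TEMPORAL_CAL = 1.0  # refined below at import, once, from the seed's spectrum


def _measure_temporal_cal() -> float:
    n = 1 << 16
    fs = 64.0
    t = np.arange(n) / fs
    h = t**2 * np.exp(-3.5 * t) * np.sin(2 * np.pi * t)
    spec = np.abs(np.fft.rfft(h))
    f = np.fft.rfftfreq(n, 1 / fs)
    return float(f[np.argmax(spec)])


_TEMPORAL_CAL = _measure_temporal_cal()


@dataclass(frozen=True)
class CorticalFilterSpec:
    """One modulation filter: rate (Hz), scale (c/o), direction, phases."""

    rate: float
    scale: float
    direction: str
    phase_t: float = 0.0  # magnitude mode: characteristic phases are zero
    phase_f: float = 0.0

    def __post_init__(self) -> None:
        if self.rate not in RATES or self.scale not in SCALES:
            raise ValueError("rate/scale must come from the model lists")
        if self.direction not in DIRECTIONS:
            raise ValueError("direction must be 'up' or 'down'")


def build_filterbank() -> list[CorticalFilterSpec]:
    """All 242 modulation filters (11 rates x 11 scales x 2 directions)."""
    return [
        CorticalFilterSpec(rate=r, scale=s, direction=d)
        for s in SCALES
        for r in RATES
        for d in DIRECTIONS
    ]


def rate_direction_labels(rates=RATES) -> list[tuple[float, str]]:
    """Order of the tensor's rate axis: upward rates then downward rates."""
    return [(r, "up") for r in rates] + [(r, "down") for r in rates]


# ---------------------------------------------------------------------------
# kernels


def temporal_kernel(rate: float, frame_rate: float, tau_max: float = 6.0) -> np.ndarray:
    """Complex analytic temporal kernel for one rate (downward-selective when
    paired with the analytic spectral kernel; conjugate for upward)."""
    eff = rate / _TEMPORAL_CAL
    n = max(int(np.ceil(tau_max / eff * frame_rate)), 8)
    t = np.arange(n) / frame_rate
    tau = eff * t
    h = eff * tau**2 * np.exp(-3.5 * tau) * np.sin(2 * np.pi * tau)
    return hilbert(h)


def spectral_kernel(
    scale: float, n_channels: int = N_CHANNELS, dx: float = CHANNEL_STEP_OCT
) -> np.ndarray:
    """Complex analytic Gabor (Ricker) kernel on the wrapped octave grid."""
    k = np.arange(n_channels)
    x = ((k + n_channels // 2) % n_channels - n_channels // 2) * dx
    u = _SPECTRAL_CAL * scale * x
    h = scale * (1.0 - u**2) * np.exp(-(u**2) / 2.0)
    return hilbert(h)


# ---------------------------------------------------------------------------
# containers


@dataclass
class CorticalTensor:
    """Time-averaged magnitude responses over frequency x rate x scale.

    Axis order (n_channels, 2 * n_rates, n_scales); the rate axis lists the
    upward rates in ascending order followed by the downward rates.
    """

    r: np.ndarray
    duration: float
    rates: tuple = RATES
    scales: tuple = SCALES

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 3 or self.r.shape[1] != 2 * len(self.rates) or self.r.shape[
            2
        ] != len(self.scales):
            raise ValueError("tensor shape must be (channels, 2*rates, scales)")
        if np.any(self.r < 0) or not np.all(np.isfinite(self.r)):
            raise ValueError("tensor entries must be finite and non-negative")

    @property
    def shape(self):
        return self.r.shape

    def ravel(self) -> np.ndarray:
        return self.r.ravel()


@dataclass
class ScaleRateMatrix:
    """Modulation energy collapsed over frequency: (rate-direction x scale)."""

    energy: np.ndarray
    rates: tuple = RATES
    scales: tuple = SCALES

    def __post_init__(self) -> None:
        self.energy = np.asarray(self.energy, dtype=float)
        if np.any(self.energy < 0):
            raise ValueError("energies must be non-negative")

    def argmax(self) -> tuple[float, str, float]:
        """(rate, direction, scale) of the peak entry."""
        i, j = np.unravel_index(np.argmax(self.energy), self.energy.shape)
        rate, direction = rate_direction_labels(self.rates)[i]
        return rate, direction, self.scales[j]

    def to_csv(self, path) -> None:
        import pandas as pd

        labels = [f"{r:g}Hz_{d}" for r, d in rate_direction_labels(self.rates)]
        pd.DataFrame(self.energy, index=labels, columns=[f"{s:g}cpo" for s in self.scales]).to_csv(path)


@dataclass
class SeparableResponse:
    """1-D rate-filter and scale-filter magnitudes and their 4224-stack."""

    rf: np.ndarray  # (22, 128)
    sf: np.ndarray  # (11, 128)

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate([self.rf.ravel(), self.sf.ravel()])


# ---------------------------------------------------------------------------
# the joint transform


def _joint_transform(
    z: np.ndarray,
    frame_rate: float,
    dx: float,
    rates,
    scales,
) -> np.ndarray:
    """Magnitude responses of the directional joint filterbank, time-averaged.

    Returns (n_channels, 2 * len(rates), len(scales)).  Linear causal
    convolution in time (zero-padded FFT), circular along channels.
    """
    nc, nt = z.shape
    if nt == 0:
        raise ValueError("empty spectrogram")
    kts = [temporal_kernel(r, frame_rate) for r in rates]
    lt_max = max(k.size for k in kts)
    if nt < min(k.size for k in kts):
        logger.warning(
            "spectrogram (%d frames) shorter than the slowest filter support; zero-padding",
            nt,
        )
    nfft = next_fast_len(nt + lt_max - 1)
    hs_all = np.stack([fft(spectral_kernel(s, nc, dx)) for s in scales])  # (ns, nc)
    zft = fft(fft(z, axis=0), n=nfft, axis=1)

    out = np.empty((nc, 2 * len(rates), len(scales)))
    for ir, kt in enumerate(kts):
        ht_down = fft(kt, nfft)
        for d, ht in ((0, np.conj(ht_down[np.r_[0, nfft - 1 : 0 : -1]])), (1, ht_down)):
            # d=0 upward: DFT of the conjugated time kernel; d=1 downward
            a = ifft(zft * ht[None, :], axis=1)[:, :nt]
            resp = ifft(hs_all[:, :, None] * a[None, :, :], axis=1)
            out[:, d * len(rates) + ir, :] = np.abs(resp).mean(axis=2).T
    return out


def cortical_transform(spec: AuditorySpectrogram) -> CorticalTensor:
    """Full joint modulation analysis: 128 x 22 x 11 magnitude tensor."""
    if spec.n_channels != N_CHANNELS:
        raise ValueError("full transform expects the 128-channel spectrogram")
    r = _joint_transform(spec.z, spec.frame_rate, CHANNEL_STEP_OCT, RATES, SCALES)
    return CorticalTensor(r, duration=spec.n_frames / spec.frame_rate)


def scale_rate_view(t: CorticalTensor, reduce: str = "mean") -> ScaleRateMatrix:
    """Collapse the tensor over frequency to the scale-rate display."""
    if reduce == "mean":
        e = t.r.mean(axis=0)
    elif reduce == "sum":
        e = t.r.sum(axis=0)
    else:
        raise ValueError("reduce must be 'mean' or 'sum'")
    return ScaleRateMatrix(e, t.rates, t.scales)


def rate_marginal(t: CorticalTensor) -> np.ndarray:
    """Energy per rate, combining directions, frequency and scale."""
    m = t.r.sum(axis=(0, 2))
    n = len(t.rates)
    return m[:n] + m[n:]


# ---------------------------------------------------------------------------
# separable / global / undersampled variants


def _circular_analytic_temporal(rate: float, frame_rate: float, n: int) -> np.ndarray:
    """Temporal transfer function on the note's own n-frame circular grid,
    exactly one-sided in the DFT domain."""
    kt = temporal_kernel(rate, frame_rate)
    h = np.real(kt)  # fold the real seed onto the circular grid
    if h.size < n:
        h = np.pad(h, (0, n - h.size))
    else:
        pad = (-h.size) % n
        h = np.pad(h, (0, pad)).reshape(-1, n).sum(axis=0)
    return fft(hilbert(h))


def separable_transform(spec: AuditorySpectrogram) -> SeparableResponse:
    """Independent 1-D modulation analysis along time and along frequency.

    Rate filters are applied per channel (circular in time), scale filters
    per frame (circular along the tonotopic axis); magnitudes are
    time-averaged.  Upward and downward rows use conjugate kernels, whose
    magnitudes coincide for real spectrograms, so both halves of the rate
    block are populated with the same values.
    """
    z = spec.z
    nc, nt = z.shape
    n_r = len(RATES)
    rf = np.empty((2 * n_r, nc))
    zt = fft(z, axis=1)
    for ir, rate in enumerate(RATES):
        ht = _circular_analytic_temporal(rate, spec.frame_rate, nt)
        y = ifft(zt * ht[None, :], axis=1)
        m = np.abs(y).mean(axis=1)
        rf[ir] = m
        rf[n_r + ir] = m
    sf = np.empty((len(SCALES), nc))
    zf = fft(z, axis=0)
    for isc, sc in enumerate(SCALES):
        hs = fft(spectral_kernel(sc, nc, CHANNEL_STEP_OCT))
        y = ifft(hs[:, None] * zf, axis=0)
        sf[isc] = np.abs(y).mean(axis=1)
    return SeparableResponse(rf=rf, sf=sf)


def global_modulation(spec: AuditorySpectrogram) -> np.ndarray:
    """Rate and scale marginals integrated over frequency: a 33-vector."""
    sep = separable_transform(spec)
    return np.concatenate([sep.rf.sum(axis=1), sep.sf.sum(axis=1)])


def undersampled_transform(spec: AuditorySpectrogram) -> np.ndarray:
    """Coarse joint model: 64 channels x (5 rates x 2) x 6 scales = 3840."""
    z = spec.z
    if z.shape[0] % 2:
        raise ValueError("channel count must be even for 2x downsampling")
    z2 = 0.5 * (z[0::2] + z[1::2])
    r = _joint_transform(
        z2, spec.frame_rate, 2 * CHANNEL_STEP_OCT, UNDERSAMPLED_RATES, UNDERSAMPLED_SCALES
    )
    return r.ravel()


# ---------------------------------------------------------------------------
# ideal spectrogram-domain ripples (probe fixtures)


def ripple_spectrogram(
    rate_hz: float,
    scale_cpo: float,
    direction: str = "down",
    duration: float = 1.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    depth: float = 0.9,
    phase: float = 0.0,
) -> AuditorySpectrogram:
    """An ideal drifting-ripple envelope placed directly on the 128-channel
    grid — the noiseless spectrogram a moving ripple is designed to evoke."""
    if direction not in DIRECTIONS:
        raise ValueError("direction must be 'up' or 'down'")
    nt = int(round(duration * frame_rate))
    t = np.arange(nt) / frame_rate
    x = np.arange(N_CHANNELS) * CHANNEL_STEP_OCT
    sgn = 1.0 if direction == "down" else -1.0
    z = 1.0 + depth * np.cos(
        2 * np.pi * (sgn * rate_hz * t[None, :] + scale_cpo * x[:, None]) + phase
    )
    return AuditorySpectrogram(z, frame_rate, center_frequencies())


# ---------------------------------------------------------------------------
# measured receptive fields


@dataclass
class STRFRecord:
    """A lag x frequency receptive field with its bootstrap SNR.

    ``weights[i, j]`` is the gain applied to spectrogram energy at lag
    ``i * lag_step`` seconds and frequency channel ``j``; ``low_freq`` and
    ``n_octaves`` describe the frequency axis of the weights.
    """

    weights: np.ndarray
    lag_step: float
    snr: float
    low_freq: float = LOW_FREQ
    n_octaves: float = N_OCTAVES

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.lag_step <= 0:
            raise ValueError("lag_step must be positive")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("STRF weights must be finite")

    def is_aligned(self, frame_rate: float) -> bool:
        return (
            self.weights.shape[1] == N_CHANNELS
            and self.low_freq == LOW_FREQ
            and self.n_octaves == N_OCTAVES
            and abs(self.lag_step - 1.0 / frame_rate) < 1e-9
        )


def synth_strf_bank(
    n: int,
    seed: int,
    n_lags: int = 40,
    lag_step: float = 0.005,
    n_freq: int = 100,
    n_octaves: float = 5.0,
) -> list[STRFRecord]:
    """Random Gabor-like STRFs over physiological parameter ranges.

    Rates are drawn from 4–24 Hz and scales up to 1.4 peaks/octave (the
    ranges spanned by ripple reverse-correlation stimuli), directions are
    random, and SNR is uniform on [0.5, 10].  Frequency axes start at 125,
    250 or 500 Hz over 5 octaves, so records require alignment before use.
    """
    if n < 1:
        raise ValueError("need at least one STRF")
    rng = np.random.default_rng(seed)
    lags = np.arange(n_lags) * lag_step
    x = np.linspace(0.0, n_octaves, n_freq)
    out = []
    for _ in range(n):
        rate = rng.uniform(4.0, 24.0)
        scale = rng.uniform(0.05, 1.4)
        sgn = rng.choice([-1.0, 1.0])
        bf = rng.uniform(0.5, n_octaves - 0.5)
        t0 = rng.uniform(0.02, 0.08)
        sig_t = rng.uniform(0.02, 0.06)
        sig_f = rng.uniform(0.3, 1.5)
        psi = rng.uniform(0, 2 * np.pi)
        env = np.exp(
            -0.5 * ((lags[:, None] - t0) / sig_t) ** 2
            - 0.5 * ((x[None, :] - bf) / sig_f) ** 2
        )
        carrier = np.cos(
            2 * np.pi * (sgn * rate * lags[:, None] + scale * x[None, :]) + psi
        )
        w = env * carrier
        out.append(
            STRFRecord(
                weights=w,
                lag_step=lag_step,
                snr=float(rng.uniform(0.5, 10.0)),
                low_freq=float(rng.choice([125.0, 250.0, 500.0])),
                n_octaves=n_octaves,
            )
        )
    return out


def filter_by_snr(bank: list[STRFRecord], threshold: float = 2.0) -> list[STRFRecord]:
    """Keep only records whose bootstrap SNR reaches the threshold."""
    return [r for r in bank if r.snr >= threshold]


def align_strf(record: STRFRecord, frame_rate: float = DEFAULT_FRAME_RATE) -> STRFRecord:
    """Scale and shift a record onto the model grid: the source octave span
    is stretched to 5.3 octaves over 128 channels (cubic interpolation) and
    the lag axis is resampled to the spectrogram frame period."""
    w = record.weights
    src_x = np.linspace(0.0, record.n_octaves, w.shape[1])
    tgt_x = np.arange(N_CHANNELS) * CHANNEL_STEP_OCT * (record.n_octaves / N_OCTAVES)
    wf = interp1d(src_x, w, kind="cubic", axis=1, bounds_error=False, fill_value=0.0)(tgt_x)
    src_t = np.arange(w.shape[0]) * record.lag_step
    tgt_step = 1.0 / frame_rate
    tgt_t = np.arange(0.0, src_t[-1] + tgt_step / 2, tgt_step)
    wt = interp1d(src_t, wf, kind="cubic", axis=0, bounds_error=False, fill_value=0.0)(tgt_t)
    return STRFRecord(
        weights=wt, lag_step=tgt_step, snr=record.snr, low_freq=LOW_FREQ, n_octaves=N_OCTAVES
    )


def strf_transform(
    spec: AuditorySpectrogram, bank: list[STRFRecord], snr_threshold: float = 2.0
) -> np.ndarray:
    """Responses of a bank of measured STRFs, stacked across the tonotopy.

    Each record is convolved with the spectrogram (the STRF is shifted
    across the tonotopic axis; linear, centered along frequency, causal
    along time), the absolute response is averaged over the note duration,
    and the per-record 128-vectors are concatenated.  Records below the SNR
    threshold are discarded first.
    """
    kept = filter_by_snr(bank, snr_threshold)
    if not kept:
        raise ValueError("no STRF passes the SNR threshold")
    for rec in kept:
        if not rec.is_aligned(spec.frame_rate):
            raise ValueError(
                "STRF grid does not match the 128-channel spectrogram grid; "
                "run cortimbre.cortical.align_strf first"
            )
    z = spec.z
    nc, nt = z.shape
    n_lags = max(r.weights.shape[0] for r in kept)
    nf_t = next_fast_len(nt + n_lags - 1)
    nf_f = next_fast_len(2 * nc - 1)
    zf = np.fft.rfftn(z, s=(nf_f, nf_t))
    half = nc // 2
    out = np.empty((len(kept), nc))
    for i, rec in enumerate(kept):
        k = rec.weights.T  # (freq, lag)
        kf = np.fft.rfftn(k, s=(nf_f, nf_t))
        y = np.fft.irfftn(zf * kf, s=(nf_f, nf_t))
        # centered slice along frequency, causal slice along time
        rows = (np.arange(nc) + half) % nf_f
        out[i] = np.abs(y[rows][:, :nt]).mean(axis=1)
    return out.ravel()


# ---------------------------------------------------------------------------
# STRF bank I/O


def save_strf_bank(path, bank: list[STRFRecord]) -> None:
    with h5py.File(path, "w") as f:
        for i, rec in enumerate(bank):
            g = f.create_group(f"unit{i:05d}")
            g.create_dataset("weights", data=rec.weights)
            g.attrs["lag_step"] = rec.lag_step
            g.attrs["snr"] = rec.snr
            g.attrs["low_freq"] = rec.low_freq
            g.attrs["n_octaves"] = rec.n_octaves


def load_strf_bank(path) -> list[STRFRecord]:
    bank = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            bank.append(
                STRFRecord(
                    weights=g["weights"][()],
                    lag_step=float(g.attrs["lag_step"]),
                    snr=float(g.attrs["snr"]),
                    low_freq=float(g.attrs["low_freq"]),
                    n_octaves=float(g.attrs["n_octaves"]),
                )
            )
    return bank
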