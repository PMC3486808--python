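"""Early auditory pathway: waveform -> auditory spectrogram z(t, f).

The stages mirror peripheral and midbrain processing:

1. **Cochlear filterbank** — 128 constant-Q bandpass filters equally spaced
   on a log-frequency axis spanning 5.3 octaves above 180 Hz
   (``CF_k = 180 * 2**(k * 5.3 / 127)``).  The filters are complex
   (analytic) gammatones, so each channel carries a narrowband envelope and
   phase.
2. **Hair-cell transduction** — a temporal first difference (high-pass AC
   coupling), rectification realized as the analytic-signal magnitude,
   an optional compressive nonlinearity (off by default so the stage is
   positively homogeneous and testable), and a one-pole low-pass at 2 kHz.
3. **Lateral inhibition** — a first difference across adjacent channels
   followed by half-wave rectification, sharpening the tonotopic profile.
4. **Midbrain integration** — leaky integration with a 4-ms time constant,
   then framing at the spectrogram frame rate.

All stages are positively homogeneous when compression is off, and the
rectified-envelope formulation makes the output exactly invariant to a sign
flip of the waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal
from scipy.fft import fft, ifft, next_fast_len

from .synth import TARGET_FS, Waveform

N_CHANNELS = 128
LOW_FREQ = 180.0
N_OCTAVES = 5.3
DEFAULT_FRAME_RATE = 500.0
#: octave spacing between adjacent channels
CHANNEL_STEP_OCT = N_OCTAVES / (N_CHANNELS - 1)


def center_frequencies(
    n_channels: int = N_CHANNELS, low_freq: float = LOW_FREQ, n_octaves: float = N_OCTAVES
) -> np.ndarray:
    """Log-spaced characteristic frequencies CF_k = low * 2**(k * span / (n-1))."""
    k = np.arange(n_channels)
    return low_freq * 2.0 ** (k * n_octaves / (n_channels - 1))


@dataclass
class AuditorySpectrogram:
    """Non-negative time-frequency representation z(t, f).

    ``z`` is (128 channels x frames); ``cfs`` are the channel characteristic
    frequencies in Hz, strictly increasing over 5.3 octaves from 180 Hz.
    """

    z: np.ndarray
    frame_rate: float
    cfs: np.ndarray = field(default_factory=center_frequencies)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.cfs = np.asarray(self.cfs, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.cfs.size:
            raise ValueError("z must be (n_channels x n_frames) matching cfs")
        if np.any(np.diff(self.cfs) <= 0):
            raise ValueError("cfs must be strictly increasing")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("spectrogram must be finite")
        if np.any(self.z < -1e-12):
            raise ValueError("spectrogram entries must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.z.shape[0]

    @property
    def n_frames(self) -> int:
        return self.z.shape[1]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("z", data=self.z)
            f.create_dataset("cfs", data=self.cfs)
            f.attrs["frame_rate"] = self.frame_rate

    @classmethod
    def from_hdf5(cls, path) -> "AuditorySpectrogram":
        with h5py.File(path, "r") as f:
            return cls(f["z"][()], float(f.attrs["frame_rate"]), f["cfs"][()])


# ---------------------------------------------------------------------------
# cochlear filterbank

#: quality factor (CF / 3-dB bandwidth) of the cochlear filters; a broad,
#: ringing-limited compromise consistent with 24-channel/octave spacing
COCHLEAR_Q = 8.0
_GAMMA_ORDER = 4

_fb_cache: dict = {}


def _gammatone_ir(cf: float, fs: float, q: float = COCHLEAR_Q) -> np.ndarray:
    """Complex (analytic) gammatone impulse response, truncated where the
    envelope falls below 1e-5 of its peak."""
    # order-4 gammatone: envelope t^3 exp(-2 pi b t); 3-dB bandwidth of the
    # magnitude response is approximately 0.87 * 2 * b for this order
    b = cf / (q * 2.0 * 0.87)
    t_peak = 3.0 / (2 * np.pi * b)
    # envelope(t)/envelope(t_peak) < 1e-5 bound, solved numerically once
    t_max = t_peak * 8.0
    n = int(np.ceil(t_max * fs))
    t = np.arange(1, n + 1) / fs
    env = t**3 * np.exp(-2 * np.pi * b * t)
    ir = env * np.exp(2j * np.pi * cf * t)
    return ir / np.sum(env)


def _filterbank_transfer(fs: float, nfft: int, cfs: np.ndarray) -> np.ndarray:
    key = (fs, nfft, cfs.shape[0], float(cfs[0]), float(cfs[-1]))
    if key not in _fb_cache:
        H = np.empty((cfs.size, nfft), dtype=complex)
        for i, cf in enumerate(cfs):
            ir = _gammatone_ir(cf, fs)
            H[i] = fft(ir, nfft)
        _fb_cache[key] = H
    return _fb_cache[key]


def auditory_spectrogram(
    w: Waveform,
    frame_rate: float = DEFAULT_FRAME_RATE,
    compression: bool = False,
    lowpass_cutoff: float = 2000.0,
) -> AuditorySpectrogram:
    """Map a 16-kHz waveform to the auditory spectrogram.

    ``frame_rate`` defaults to 500 Hz so that temporal-modulation filters up
    to 128 Hz remain below the frame Nyquist.  With ``compression`` off the
    map is positively homogeneous of degree 1.
    """
    x = np.asarray(w.samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    if int(w.sample_rate) != TARGET_FS:
        raise ValueError(
            f"waveform must be at {TARGET_FS} Hz; run cortimbre.synth.preprocess first"
        )
    fs = float(w.sample_rate)
    cfs = center_frequencies()

    # cochlear stage: analytic gammatone filterbank via FFT-domain products
    max_ir = int(np.ceil(8.0 * 3.0 / (2 * np.pi * (cfs[0] / (COCHLEAR_Q * 2 * 0.87))) * fs))
    nfft = next_fast_len(x.size + max_ir)
    H = _filterbank_transfer(fs, nfft, cfs)
    X = fft(x, nfft)
    y = ifft(X[None, :] * H, axis=1)[:, : x.size]

    # hair cell: temporal high-pass (first difference of the analytic
    # signal), envelope magnitude, optional compression, one-pole low-pass
    d = np.empty_like(y)
    d[:, 0] = y[:, 0]
    d[:, 1:] = y[:, 1:] - y[:, :-1]
    env = np.abs(d)
    if compression:
        env = np.tanh(env)
    a_lp = np.exp(-2 * np.pi * lowpass_cutoff / fs)
    env = signal.lfilter([1.0 - a_lp], [1.0, -a_lp], env, axis=1)

    # lateral inhibitory network: difference across adjacent channels + HWR
    lin = np.empty_like(env)
    lin[0] = env[0]
    lin[1:] = env[1:] - env[:-1]
    lin = np.maximum(lin, 0.0)

    # midbrain: leaky integration, tau = 4 ms, then framing
    a_mi = np.exp(-1.0 / (fs * 0.004))
    zi = signal.lfilter([1.0 - a_mi], [1.0, -a_mi], lin, axis=1)
    dec = int(round(fs / frame_rate))
    n_frames = int(np.ceil(x.size / fs * frame_rate))
    idx = np.minimum(np.arange(n_frames) * dec + dec - 1, x.size - 1)
    z = zi[:, idx]
    return AuditorySpectrogram(np.maximum(z, 0.0), frame_rate, cfs)


def spectral_profile(spec: AuditorySpectrogram) -> np.ndarray:
    """Time-average of each channel: the 128-point auditory spectrum."""
    if spec.n_frames == 0:
        raise ValueError("empty spectrogram")
    return spec.z.mean(axis=1)


def filterbank_response(freq: float, fs: float = TARGET_FS) -> np.ndarray:
    """Directly evaluated magnitude response of every cochlear filter at a
    single frequency (independent oracle for tone-placement tests)."""
    cfs = center_frequencies()
    out = np.empty(cfs.size)
    for i, cf in enumerate(cfs):
        ir = _gammatone_ir(cf, fs)
        n = np.arange(1, ir.size + 1)
        out[i] = np.abs(np.sum(ir * np.exp(-2j * np.pi * freq * n / fs)))
    return out
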