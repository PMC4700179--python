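"""Signal container, WAV I/O, Gammatone filterbank, and band envelopes.

All downstream synthesis and descriptor extraction operates on :class:`Signal`
objects (mono, finite samples) and their 24-band Gammatone decompositions.
Filterbank centres are equally spaced on the ERB-rate scale (Glasberg & Moore,
1990).  Filtering is performed in the frequency domain with the magnitude
response of a 4th-order gammatone and zero phase, so that

* decomposition is exactly linear,
* every band (and hence every envelope) is time-aligned with the input, and
* summing the bands reconstructs the input up to a smooth spectral ripple
  inside the filterbank's frequency range (the analysis-sum is approximately,
  not exactly, allpass).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "Signal",
    "FilterbankSpec",
    "BandDecomposition",
    "Envelope",
    "erb_rate",
    "erb_rate_inverse",
    "erb_bandwidth",
    "read_wav",
    "write_wav",
    "design_filterbank",
    "decompose",
    "reconstruct",
    "band_envelope",
]

DEFAULT_SAMPLE_RATE = 44_100


@dataclass
class Signal:
    """A mono audio signal: samples (float64), sample rate in Hz, and a label."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Signal must be mono (1-D sample array)")
        if self.samples.size == 0:
            raise ValueError("Signal must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Signal contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.sample_rate

    def copy(self, label: str | None = None) -> "Signal":
        return Signal(self.samples.copy(), self.sample_rate,
                      self.label if label is None else label)


@dataclass
class FilterbankSpec:
    """ERB-spaced Gammatone filterbank layout."""

    center_freqs: np.ndarray
    fmin: float
    fmax: float
    order: int = 4
    spacing: str = "erb"

    def __post_init__(self) -> None:
        self.center_freqs = np.asarray(self.center_freqs, dtype=np.float64)
        if self.center_freqs.size < 2:
            raise ValueError("need at least 2 bands")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValueError("center_freqs must be strictly increasing")
        if not (0 < self.fmin <= self.center_freqs[0]):
            raise ValueError("fmin must satisfy 0 < fmin <= center_freqs[0]")

    @property
    def n_bands(self) -> int:
        return self.center_freqs.size

    def to_json(self) -> str:
        return json.dumps({
            "center_freqs": self.center_freqs.tolist(),
            "fmin": self.fmin, "fmax": self.fmax,
            "order": self.order, "spacing": self.spacing,
        })

    @classmethod
    def from_json(cls, text: str) -> "FilterbankSpec":
        d = json.loads(text)
        return cls(np.asarray(d["center_freqs"]), d["fmin"], d["fmax"],
                   d.get("order", 4), d.get("spacing", "erb"))


@dataclass
class BandDecomposition:
    """Per-band signals (n_bands x n_samples) of one Signal."""

    bands: np.ndarray
    spec: FilterbankSpec
    sample_rate: int

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        if self.bands.ndim != 2:
            raise ValueError("bands must be 2-D")
        if self.bands.shape[0] != self.spec.n_bands:
            raise ValueError("row count must equal spec.n_bands")

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    @property
    def n_samples(self) -> int:
        return self.bands.shape[1]


@dataclass
class Envelope:
    """Nonnegative amplitude envelope of one filter band."""

    values: np.ndarray
    sample_rate: int
    cutoff: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")


# --------------------------------------------------------------------------
# ERB-rate scale (Glasberg & Moore 1990)

def erb_rate(f: np.ndarray | float) -> np.ndarray | float:
    """Map frequency in Hz to the ERB-rate (ERB-number) scale."""
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f, dtype=np.float64))


def erb_rate_inverse(e: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`erb_rate`."""
    return (10.0 ** (np.asarray(e, dtype=np.float64) / 21.4) - 1.0) / 0.00437


def erb_bandwidth(f: np.ndarray | float) -> np.ndarray | float:
    """Equivalent rectangular bandwidth (Hz) of the auditory filter at f."""
    return 24.7 * (1.0 + 0.00437 * np.asarray(f, dtype=np.float64))


# --------------------------------------------------------------------------
# WAV I/O (scipy.io.wavfile: PCM 16/24/32 and float32/64)

def read_wav(path) -> Signal:
    """Read a WAV file as a mono float Signal in [-1, 1].

    Stereo files are reduced to their left channel.  Integer PCM is scaled by
    the full-scale value of its bit depth.
    """
    rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    if data.ndim == 2:  # left channel only
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding: {data.dtype}")
    import os
    label = os.path.splitext(os.path.basename(str(path)))[0]
    return Signal(samples, int(rate), label)


def write_wav(signal: Signal, path, subtype: str = "float32") -> None:
    """Write a Signal to WAV (float32 by default; 'pcm16' also supported)."""
    if subtype == "float32":
        wavfile.write(path, signal.sample_rate,
                      signal.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 1.0)
        wavfile.write(path, signal.sample_rate,
                      np.round(clipped * 32767.0).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype: {subtype}")


# --------------------------------------------------------------------------
# Filterbank

def design_filterbank(n_bands: int = 24, fmin: float = 50.0,
                      fmax: float = 16_000.0,
                      sample_rate: int = DEFAULT_SAMPLE_RATE) -> FilterbankSpec:
    """Place ``n_bands`` centres equally spaced on the ERB-rate scale.

    The first and last centres sit exactly at ``fmin`` and ``fmax``.
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if not (0 < fmin < fmax):
        raise ValueError("need 0 < fmin < fmax")
    if fmax >= sample_rate / 2:
        raise ValueError("fmax must lie below the Nyquist frequency")
    centers = erb_rate_inverse(
        np.linspace(erb_rate(fmin), erb_rate(fmax), n_bands))
    centers[0], centers[-1] = fmin, fmax  # kill round-trip rounding
    return FilterbankSpec(centers, fmin=fmin, fmax=fmax)


def _band_responses(spec: FilterbankSpec, n_samples: int,
                    sample_rate: int) -> np.ndarray:
    """Magnitude responses (n_bands x n_rfft) of 4th-order gammatone filters.

    |H(f)| = [1 + ((f - fc)/b)^2]^(-order/2) with b = 1.019 ERB(fc), peak 1
    at the centre frequency.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    fc = spec.center_freqs[:, None]
    b = 1.019 * erb_bandwidth(spec.center_freqs)[:, None]
    return (1.0 + ((freqs[None, :] - fc) / b) ** 2) ** (-spec.order / 2.0)


def decompose(signal: Signal, spec: FilterbankSpec | None = None) -> BandDecomposition:
    """Split a signal into Gammatone bands (zero-phase, exactly linear)."""
    if spec is None:
        spec = design_filterbank(sample_rate=signal.sample_rate)
    if spec.fmax >= signal.sample_rate / 2:
        raise ValueError("filterbank fmax at or above Nyquist for this signal")
    spectrum = np.fft.rfft(signal.samples)
    H = _band_responses(spec, signal.n_samples, signal.sample_rate)
    bands = np.fft.irfft(H * spectrum[None, :], n=signal.n_samples, axis=1)
    return BandDecomposition(bands, spec, signal.sample_rate)


def reconstruct(decomposition: BandDecomposition, label: str = "") -> Signal:
    """Sum the bands.  This is summation, not exact inversion: the summed
    magnitude response carries a ripple inside [fmin, fmax] (about +/-2 dB for
    the default 24-band design) and rolls off outside it."""
    return Signal(decomposition.bands.sum(axis=0),
                  decomposition.sample_rate, label)


# --------------------------------------------------------------------------
# Envelope extraction

def band_envelope(band: np.ndarray, sample_rate: int,
                  cutoff_hz: float = 30.0, order: int = 4) -> Envelope:
    """Half-wave rectification followed by a zero-phase Butterworth low-pass.

    The result is nonnegative, time-aligned with the band (filtfilt), and
    proportional to — not equal to — the band's instantaneous amplitude (the
    rectifier keeps 1/pi of a sinusoid's amplitude in its DC component).
    """
    band = np.asarray(band, dtype=np.float64)
    if cutoff_hz >= sample_rate / 2:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    rectified = np.maximum(band, 0.0)
    sos = butter(order, cutoff_hz, btype="low", fs=sample_rate, output="sos")
    smooth = sosfiltfilt(sos, rectified)
    return Envelope(np.maximum(smooth, 0.0), sample_rate, cutoff_hz)


def analytic_envelope(samples: np.ndarray,
                      sample_rate: int,
                      smooth_cutoff_hz: float | None = None) -> np.ndarray:
    """Magnitude of the analytic (Hilbert) signal, optionally low-passed."""
    env = np.abs(hilbert(np.asarray(samples, dtype=np.float64)))
    if smooth_cutoff_hz is not None:
        sos = butter(4, smooth_cutoff_hz, btype="low", fs=sample_rate,
                     output="sos")
        env = np.maximum(sosfiltfilt(sos, env), 0.0)
    return env
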