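"""Scalar acoustic timbre descriptors.

Thirty-four descriptors per stimulus: twelve temporal measures taken from the
Hilbert amplitude envelope (attack, decay, release, log-attack time, slopes,
temporal centroid, effective duration, energy modulation, RMS envelope
median/IQR) and eleven spectral measures taken per 25-ms frame of an
ERB-spaced Gammatone band-energy decomposition, each summarized by its median
and interquartile range across frames (centroid, spread, skew, kurtosis,
slope, decrease, rolloff, spectrotemporal variation, frame energy, flatness,
crest).

Thresholds that the descriptor literature leaves open are explicit keyword
arguments with logged defaults: attack window 10 %–90 % of the envelope
maximum, effective duration at 40 %, release at 10 %, rolloff at 95 % of
cumulative energy.  Input signals are peak-normalized before analysis, so
every descriptor is invariant to positive rescaling of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import FilterbankSpec, Signal, analytic_envelope, decompose, design_filterbank

__all__ = [
    "TEMPORAL_NAMES",
    "FRAME_DESCRIPTOR_NAMES",
    "DESCRIPTOR_NAMES",
    "TemporalEnvelopeProfile",
    "SpectralFrameSeries",
    "DescriptorVector",
    "temporal_envelope",
    "temporal_descriptors",
    "spectral_frame_analysis",
    "frame_descriptors",
    "summarize_frames",
    "descriptor_vector",
    "descriptor_table",
]

TEMPORAL_NAMES = [
    "attack_duration",
    "decay_duration",
    "release",
    "log_attack_time",
    "attack_slope",
    "decrease_slope",
    "temporal_centroid",
    "effective_duration",
    "energy_mod_frequency",
    "energy_mod_amplitude",
    "rms_env_med",
    "rms_env_iqr",
]

FRAME_DESCRIPTOR_NAMES = [
    "centroid",
    "spread",
    "skew",
    "kurtosis",
    "slope",
    "decrease",
    "rolloff",
    "spectemp_var",
    "frame_energy",
    "flatness",
    "crest",
]

DESCRIPTOR_NAMES = TEMPORAL_NAMES + [
    f"{name}_{stat}" for name in FRAME_DESCRIPTOR_NAMES for stat in ("med", "iqr")
]
assert len(DESCRIPTOR_NAMES) == 34


@dataclass
class TemporalEnvelopeProfile:
    values: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("envelope must be nonnegative")


@dataclass
class SpectralFrameSeries:
    frame_energies: np.ndarray  # n_frames x n_bands
    frame_times: np.ndarray
    band_freqs: np.ndarray
    frame_len: float

    def __post_init__(self) -> None:
        self.frame_energies = np.asarray(self.frame_energies, dtype=np.float64)
        if np.any(self.frame_energies < 0):
            raise ValueError("frame energies must be nonnegative")


@dataclass
class DescriptorVector:
    values: np.ndarray
    names: list = field(default_factory=lambda: list(DESCRIPTOR_NAMES))
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size != len(self.names):
            raise ValueError("value/name length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptors must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.label)


def temporal_envelope(signal: Signal,
                      smooth_cutoff_hz: float | None = None) -> TemporalEnvelopeProfile:
    """Hilbert-transform amplitude envelope, optionally low-pass smoothed."""
    env = analytic_envelope(signal.samples, signal.sample_rate, smooth_cutoff_hz)
    return TemporalEnvelopeProfile(env, signal.sample_rate)


def _first_crossing(env: np.ndarray, level: float) -> int:
    idx = np.flatnonzero(env >= level)
    return int(idx[0]) if idx.size else 0


def temporal_descriptors(profile: TemporalEnvelopeProfile,
                         attack_lo: float = 0.10, attack_hi: float = 0.90,
                         effective_frac: float = 0.40,
                         release_frac: float = 0.10,
                         frame_len: float = 0.025,
                         hop: float | None = None) -> dict:
    """The twelve temporal descriptors of one envelope profile.

    Attack spans the first crossings of ``attack_lo`` and ``attack_hi`` times
    the envelope maximum; log-attack time is log10 of that span (floored at
    one sample).  Decay runs from the envelope peak to the last crossing of
    the release threshold; release from there to the signal end.  Energy
    modulation is the dominant spectral peak of the mean-removed envelope
    above 1 Hz (zero-padded FFT for sub-bin frequency resolution).
    """
    env = profile.values
    fs = profile.sample_rate
    n = env.size
    out = dict.fromkeys(TEMPORAL_NAMES, 0.0)
    m = env.max() if n else 0.0
    if m <= 0:
        warnings.warn("all-zero envelope: temporal descriptors set to 0")
        out["log_attack_time"] = np.log10(1.0 / fs)
        return out

    i_lo = _first_crossing(env, attack_lo * m)
    i_hi = _first_crossing(env, attack_hi * m)
    i_peak = int(np.argmax(env))
    attack = max(i_hi - i_lo, 1) / fs
    out["attack_duration"] = attack
    out["log_attack_time"] = float(np.log10(attack))
    out["attack_slope"] = (attack_hi - attack_lo) / attack  # normalized a/s

    above_rel = np.flatnonzero(env >= release_frac * m)
    i_rel = int(above_rel[-1]) if above_rel.size else n - 1
    out["decay_duration"] = max(i_rel - i_peak, 0) / fs
    out["release"] = (n - 1 - i_rel) / fs

    # log-amplitude slope from the peak onwards (decrease slope)
    tail = env[i_peak:]
    keep = tail > 1e-6 * m
    if keep.sum() >= 2:
        t = np.flatnonzero(keep) / fs
        y = np.log(tail[keep] / m)
        out["decrease_slope"] = float(np.polyfit(t, y, 1)[0])

    energy = np.square(env)
    out["temporal_centroid"] = float(
        np.sum(np.arange(n) / fs * energy) / np.sum(energy))
    out["effective_duration"] = float(np.sum(env >= effective_frac * m) / fs)

    # energy modulation: dominant envelope spectral peak above 1 Hz
    centered = env - env.mean()
    n_fft = int(2 ** np.ceil(np.log2(max(n * 4, 1024))))
    spec = np.abs(np.fft.rfft(centered, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    valid = freqs >= 1.0
    if np.any(valid) and spec[valid].max() > 0:
        j = int(np.argmax(spec[valid]))
        out["energy_mod_frequency"] = float(freqs[valid][j])
        # amplitude of that component relative to the mean envelope level
        out["energy_mod_amplitude"] = float(
            2.0 * spec[valid][j] / n / max(env.mean(), 1e-12))

    hop = frame_len / 2 if hop is None else hop
    starts = np.arange(0, max(n - int(frame_len * fs), 0) + 1,
                       max(int(hop * fs), 1))
    width = min(int(frame_len * fs), n)
    rms = np.array([np.sqrt(np.mean(np.square(env[s:s + width])))
                    for s in starts]) if starts.size else np.array([0.0])
    out["rms_env_med"] = float(np.median(rms))
    out["rms_env_iqr"] = float(np.percentile(rms, 75) - np.percentile(rms, 25))
    return out


def spectral_frame_analysis(signal: Signal,
                            spec: FilterbankSpec | None = None,
                            frame_len: float = 0.025,
                            hop: float | None = None) -> SpectralFrameSeries:
    """Per-frame, per-band energies of a Gammatone decomposition.

    Frame energy is the mean squared band amplitude in each 25-ms frame;
    frames hop by half a frame by default.
    """
    if spec is None:
        spec = design_filterbank(sample_rate=signal.sample_rate)
    width = int(round(frame_len * signal.sample_rate))
    if width > signal.n_samples:
        raise ValueError("frame longer than signal")
    hop = frame_len / 2 if hop is None else hop
    step = max(int(round(hop * signal.sample_rate)), 1)
    bands = decompose(signal, spec).bands
    starts = np.arange(0, signal.n_samples - width + 1, step)
    energies = np.empty((starts.size, spec.n_bands))
    sq = np.square(bands)
    csum = np.concatenate([np.zeros((spec.n_bands, 1)), np.cumsum(sq, axis=1)],
                          axis=1)
    for i, s in enumerate(starts):
        energies[i] = (csum[:, s + width] - csum[:, s]) / width
    times = (starts + width / 2) / signal.sample_rate
    return SpectralFrameSeries(np.maximum(energies, 0.0), times,
                               spec.center_freqs.copy(), frame_len)


def frame_descriptors(frame_energies: np.ndarray,
                      band_freqs: np.ndarray,
                      rolloff_frac: float = 0.95) -> np.ndarray:
    """Eleven spectral descriptors for every frame (n_frames x 11).

    Moments use the energy distribution normalized per frame; slope is the
    least-squares slope of normalized energy against frequency; decrease the
    energy-weighted average drop relative to the first band; rolloff the
    lowest band frequency below which ``rolloff_frac`` of the energy lies;
    spectrotemporal variation is one minus the correlation between
    consecutive frames (zero for the first frame and for degenerate frames);
    flatness the geometric/arithmetic mean ratio and crest the max/mean
    ratio.  An all-zero frame yields zero moments, flatness 1 and crest 1 by
    convention (with a warning).
    """
    E = np.asarray(frame_energies, dtype=np.float64)
    if E.ndim == 1:
        E = E[None, :]
    if np.any(E < 0):
        raise ValueError("negative frame energies")
    f = np.asarray(band_freqs, dtype=np.float64)
    n_frames, n_bands = E.shape
    out = np.zeros((n_frames, len(FRAME_DESCRIPTOR_NAMES)))
    col = {name: i for i, name in enumerate(FRAME_DESCRIPTOR_NAMES)}

    totals = E.sum(axis=1)
    zero_frames = totals <= 0
    if np.any(zero_frames):
        warnings.warn(f"{int(zero_frames.sum())} all-zero frame(s)")

    for i in range(n_frames):
        e = E[i]
        tot = totals[i]
        if tot <= 0:
            out[i, col["flatness"]] = 1.0
            out[i, col["crest"]] = 1.0
            continue
        p = e / tot
        c = float(np.dot(f, p))
        spread = float(np.sqrt(np.dot((f - c) ** 2, p)))
        out[i, col["centroid"]] = c
        out[i, col["spread"]] = spread
        if spread > 0:
            z = (f - c) / spread
            out[i, col["skew"]] = float(np.dot(z ** 3, p))
            out[i, col["kurtosis"]] = float(np.dot(z ** 4, p))
        # slope of normalized energy vs frequency (least squares)
        fc = f - f.mean()
        out[i, col["slope"]] = float(np.dot(fc, p - p.mean())
                                     / np.dot(fc, fc))
        if e[1:].sum() > 0:
            k = np.arange(2, n_bands + 1)
            out[i, col["decrease"]] = float(
                np.sum((e[1:] - e[0]) / (k - 1)) / e[1:].sum())
        j_roll = min(int(np.searchsorted(np.cumsum(e), rolloff_frac * tot)),
                     n_bands - 1)
        out[i, col["rolloff"]] = float(f[j_roll])
        if i > 0 and totals[i - 1] > 0:
            prev = E[i - 1]
            sp, se = prev.std(), e.std()
            if sp > 0 and se > 0:
                r = float(np.corrcoef(prev, e)[0, 1])
                out[i, col["spectemp_var"]] = 1.0 - r
        out[i, col["frame_energy"]] = tot
        nz_geo = np.exp(np.mean(np.log(np.maximum(e, 1e-300))))
        out[i, col["flatness"]] = float(nz_geo / (tot / n_bands)) if np.all(e > 0) else 0.0
        out[i, col["crest"]] = float(e.max() / (tot / n_bands))
    return out


def summarize_frames(series: SpectralFrameSeries,
                     rolloff_frac: float = 0.95) -> dict:
    """Median and IQR of each per-frame descriptor, interleaved."""
    if series.frame_energies.shape[0] < 1:
        raise ValueError("empty frame series")
    per_frame = frame_descriptors(series.frame_energies, series.band_freqs,
                                  rolloff_frac)
    out = {}
    for j, name in enumerate(FRAME_DESCRIPTOR_NAMES):
        vals = per_frame[:, j]
        out[f"{name}_med"] = float(np.median(vals))
        out[f"{name}_iqr"] = float(np.percentile(vals, 75)
                                   - np.percentile(vals, 25))
    return out


def descriptor_vector(signal: Signal,
                      spec: FilterbankSpec | None = None,
                      smooth_cutoff_hz: float | None = 60.0,
                      **thresholds) -> DescriptorVector:
    """All 34 descriptors of one stimulus, in registry order.

    The signal is peak-normalized first, making the full vector invariant to
    positive amplitude rescaling of the input.  The temporal envelope is
    low-passed at 60 Hz by default: the raw analytic envelope of a harmonic
    tone pulses at the fundamental, which would corrupt attack and
    effective-duration measures, while modulations of interest (< ~30 Hz)
    pass unchanged.
    """
    peak = np.max(np.abs(signal.samples))
    sig = Signal(signal.samples / peak, signal.sample_rate,
                 signal.label) if peak > 0 else signal
    frame_len = thresholds.pop("frame_len", 0.025)
    hop = thresholds.pop("hop", None)
    rolloff_frac = thresholds.pop("rolloff_frac", 0.95)
    profile = temporal_envelope(sig, smooth_cutoff_hz)
    temporal = temporal_descriptors(profile, frame_len=frame_len, hop=hop,
                                    **thresholds)
    series = spectral_frame_analysis(sig, spec, frame_len=frame_len, hop=hop)
    spectral = summarize_frames(series, rolloff_frac)
    values = [temporal[k] for k in TEMPORAL_NAMES]
    values += [spectral[k] for k in DESCRIPTOR_NAMES[12:]]
    return DescriptorVector(np.asarray(values), label=signal.label)


def descriptor_table(signals: list[Signal],
                     spec: FilterbankSpec | None = None,
                     **kwargs) -> pd.DataFrame:
    """Stimuli x 34 descriptor DataFrame (rows indexed by signal label)."""
    rows = [descriptor_vector(s, spec, **kwargs).to_series() for s in signals]
    return pd.DataFrame(rows)
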