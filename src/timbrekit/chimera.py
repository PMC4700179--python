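"""Stimulus synthesis: auditory chimeras, filterband scrambling, harmonic
complexes, stimulus conditioning, and batch grid generation.

A chimera keeps the per-band temporal fine structure of one signal (the
"c-source") and imposes the per-band amplitude envelopes of another (the
"c-filter"): in every Gammatone band the source band is divided by its own
envelope and multiplied by the filter's.  Filterband scrambling (FBS) builds a
new sound from four inputs by giving each input six of the 24 bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .audio import (
    DEFAULT_SAMPLE_RATE,
    BandDecomposition,
    Envelope,
    FilterbankSpec,
    Signal,
    band_envelope,
    decompose,
    design_filterbank,
    reconstruct,
)

__all__ = [
    "ChimeraRecipe",
    "FBSAssignment",
    "condition_stimulus",
    "make_chimera",
    "fbs_scramble",
    "harmonic_complex",
    "generate_chimera_grid",
    "loudness_normalize",
    "band_envelope_correlation",
]


@dataclass
class ChimeraRecipe:
    """Labels of the fine-structure donor and the envelope donor."""

    c_source: str
    c_filter: str
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class FBSAssignment:
    """A 6/6/6/6 partition of 24 bands over four source sounds."""

    source_ids: list
    band_map: np.ndarray  # band index -> source index in 0..3

    def __post_init__(self) -> None:
        self.band_map = np.asarray(self.band_map, dtype=int)
        if len(self.source_ids) != 4:
            raise ValueError("FBS needs exactly 4 sources")
        counts = np.bincount(self.band_map, minlength=4)
        if self.band_map.size % 4 or np.any(counts != self.band_map.size // 4):
            raise ValueError("band_map must assign each source an equal share")


def condition_stimulus(signal: Signal, duration_ms: float = 500.0,
                       fade_ms: float = 20.0, peak: float = 1.0) -> Signal:
    """Fix duration, apply a raised-cosine fade-out, and normalize the peak.

    The signal is truncated (or zero-padded, with a warning) to
    ``duration_ms``; its last ``fade_ms`` are shaped by a raised-cosine fall
    from 1 to 0; the result is scaled so max |amplitude| equals ``peak``.
    """
    if fade_ms > duration_ms:
        raise ValueError("fade_ms cannot exceed duration_ms")
    n = int(round(duration_ms * signal.sample_rate / 1000.0))
    x = signal.samples[:n]
    if x.size < n:
        warnings.warn(f"{signal.label or 'signal'}: zero-padded "
                      f"{n - x.size} samples to reach {duration_ms} ms")
        x = np.concatenate([x, np.zeros(n - x.size)])
    else:
        x = x.copy()
    n_fade = int(round(fade_ms * signal.sample_rate / 1000.0))
    if n_fade > 0:
        # w(t) = (1 + cos(pi t / T))/2 over t in (0, T]; reaches 0 exactly.
        ramp = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, n_fade + 1) / n_fade))
        x[-n_fade:] *= ramp
    m = np.max(np.abs(x))
    if m > 0:
        x *= peak / m
    return Signal(x, signal.sample_rate, signal.label)


def make_chimera(c_source: Signal, c_filter: Signal,
                 spec: FilterbankSpec | None = None,
                 eps_rel: float = 1e-6, gain_cap_db: float = 40.0,
                 env_cutoff_hz: float = 30.0,
                 condition: bool = True,
                 label: str | None = None) -> Signal:
    """Impose the c-filter's band envelopes on the c-source's fine structure.

    Per band b: ``out_b = src_b / max(env(src_b), eps) * env(filt_b)`` with
    ``eps = eps_rel * peak(c_source)``; the per-band gain is additionally
    capped at ``gain_cap_db`` to avoid blowing up bands in which the source
    has almost no energy.  Bands are summed and the result conditioned
    (500 ms, 20 ms fade, peak-normalized) unless ``condition`` is False.
    """
    if c_source.sample_rate != c_filter.sample_rate:
        raise ValueError("sample-rate mismatch between c-source and c-filter")
    if c_source.n_samples != c_filter.n_samples:
        raise ValueError("length mismatch between c-source and c-filter")
    if spec is None:
        spec = design_filterbank(sample_rate=c_source.sample_rate)
    src = decompose(c_source, spec)
    flt = decompose(c_filter, spec)
    eps = eps_rel * max(np.max(np.abs(c_source.samples)), np.finfo(float).tiny)
    cap = 10.0 ** (gain_cap_db / 20.0)
    out = np.zeros(c_source.n_samples)
    for b in range(spec.n_bands):
        env_s = band_envelope(src.bands[b], src.sample_rate, env_cutoff_hz).values
        env_f = band_envelope(flt.bands[b], flt.sample_rate, env_cutoff_hz).values
        gain = np.minimum(env_f / np.maximum(env_s, eps), cap)
        out += src.bands[b] * gain
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite chimera output; increase eps_rel")
    if label is None:
        label = f"{c_source.label}-{c_filter.label}"
    sig = Signal(out, c_source.sample_rate, label)
    return condition_stimulus(sig) if condition else sig


def fbs_scramble(sounds: list[Signal],
                 assignment_or_seed: FBSAssignment | int,
                 spec: FilterbankSpec | None = None,
                 label: str = "FBS") -> Signal:
    """Filterband scrambling: each of four sounds contributes six bands.

    With an integer seed, the band partition is drawn uniformly (6/6/6/6) and
    the result is deterministic for that seed.  The scrambled bands are
    summed without further conditioning.
    """
    if len(sounds) != 4:
        raise ValueError("FBS requires exactly 4 sounds")
    rates = {s.sample_rate for s in sounds}
    lengths = {s.n_samples for s in sounds}
    if len(rates) != 1 or len(lengths) != 1:
        raise ValueError("FBS sounds must share length and sample rate")
    if spec is None:
        spec = design_filterbank(sample_rate=sounds[0].sample_rate)
    if isinstance(assignment_or_seed, FBSAssignment):
        assignment = assignment_or_seed
        if assignment.band_map.size != spec.n_bands:
            raise ValueError("band_map length must equal n_bands")
    else:
        rng = np.random.default_rng(assignment_or_seed)
        per = spec.n_bands // 4
        band_map = np.repeat(np.arange(4), per)
        rng.shuffle(band_map)
        assignment = FBSAssignment([s.label for s in sounds], band_map)
    decomps = [decompose(s, spec) for s in sounds]
    bands = np.stack([decomps[assignment.band_map[b]].bands[b]
                      for b in range(spec.n_bands)])
    return reconstruct(BandDecomposition(bands, spec, sounds[0].sample_rate),
                       label=label)


def harmonic_complex(f0: float = 311.0, n_harmonics: int = 50,
                     duration_ms: float = 500.0,
                     sample_rate: int = DEFAULT_SAMPLE_RATE,
                     label: str = "HTC") -> Signal:
    """Zero-phase harmonic tone complex: equal-amplitude cosine harmonics.

    All harmonics have zero phase at t = 0, so the first sample is the peak;
    the result is peak-normalized.
    """
    if f0 * n_harmonics >= sample_rate / 2:
        raise ValueError("requested harmonics would alias")
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    n = int(round(duration_ms * sample_rate / 1000.0))
    t = np.arange(n) / sample_rate
    k = np.arange(1, n_harmonics + 1)[:, None]
    x = np.cos(2.0 * np.pi * f0 * k * t[None, :]).sum(axis=0)
    return Signal(x / n_harmonics, sample_rate, label)


def generate_chimera_grid(sounds: list[Signal],
                          spec: FilterbankSpec | None = None,
                          **chimera_kwargs) -> list[Signal]:
    """One chimera per ordered (c-source, c-filter) pair: n sounds -> n^2.

    Outputs are labeled ``"SRC-FLT"``.  With the study-sized inventory of 21
    sounds this yields the full 441-stimulus grid.
    """
    labels = [s.label for s in sounds]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in sound inventory")
    if spec is None and sounds:
        spec = design_filterbank(sample_rate=sounds[0].sample_rate)
    return [make_chimera(src, flt, spec=spec, **chimera_kwargs)
            for src in sounds for flt in sounds]


def band_envelope_correlation(a: Signal, b: Signal,
                              spec: FilterbankSpec | None = None,
                              env_cutoff_hz: float = 30.0,
                              weight: str = "energy") -> float:
    """Mean per-band correlation between two signals' band envelopes.

    With ``weight="energy"`` each band's correlation is weighted by the
    band energy of ``a`` (bands carrying no signal, only numerical residue,
    contribute nothing); ``weight="uniform"`` averages plainly over the
    bands whose envelopes are non-constant.
    """
    if spec is None:
        spec = design_filterbank(sample_rate=a.sample_rate)
    da, db = decompose(a, spec), decompose(b, spec)
    cors, weights = [], []
    for i in range(spec.n_bands):
        ea = band_envelope(da.bands[i], a.sample_rate, env_cutoff_hz).values
        eb = band_envelope(db.bands[i], b.sample_rate, env_cutoff_hz).values
        if ea.std() == 0 or eb.std() == 0:
            continue
        cors.append(np.corrcoef(ea, eb)[0, 1])
        weights.append(np.mean(np.square(da.bands[i]))
                       if weight == "energy" else 1.0)
    if not cors:
        raise ValueError("no non-constant band envelopes to compare")
    return float(np.average(cors, weights=weights))


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def _a_weighted_rms(signal: Signal) -> float:
    # IEC 61672 A-weighting magnitude applied in the frequency domain.
    f = np.fft.rfftfreq(signal.n_samples, 1.0 / signal.sample_rate)
    f2 = np.square(np.maximum(f, 1e-6))
    ra = (12194.0 ** 2 * f2 ** 2) / (
        (f2 + 20.6 ** 2)
        * np.sqrt((f2 + 107.7 ** 2) * (f2 + 737.9 ** 2))
        * (f2 + 12194.0 ** 2))
    ra /= (12194.0 ** 2 * 1000.0 ** 4) / (
        (1000.0 ** 2 + 20.6 ** 2)
        * np.sqrt((1000.0 ** 2 + 107.7 ** 2) * (1000.0 ** 2 + 737.9 ** 2))
        * (1000.0 ** 2 + 12194.0 ** 2))
    spectrum = np.fft.rfft(signal.samples)
    weighted = np.fft.irfft(spectrum * ra, n=signal.n_samples)
    return _rms(weighted)


def loudness_normalize(signals: list[Signal], reference_label: str,
                       mode: str = "rms") -> tuple[list[Signal], dict]:
    """Scale every signal so its loudness proxy matches the reference's.

    An automatic stand-in for perceptual loudness matching: ``mode="rms"``
    equalizes plain RMS, ``mode="dba"`` A-weighted RMS.  Returns the scaled
    signals and a label -> scale-factor log.
    """
    proxy = _a_weighted_rms if mode == "dba" else (lambda s: _rms(s.samples))
    by_label = {s.label: s for s in signals}
    if reference_label not in by_label:
        raise ValueError(f"reference {reference_label!r} not in set")
    if mode == "dba":
        levels = {s.label: proxy(s) for s in signals}
    else:
        levels = {s.label: _rms(s.samples) for s in signals}
    ref = levels[reference_label]
    if ref == 0:
        raise ValueError("silent reference signal")
    factors = {}
    out = []
    for s in signals:
        if levels[s.label] == 0:
            raise ValueError(f"silent signal {s.label!r} cannot be normalized")
        k = ref / levels[s.label]
        factors[s.label] = k
        out.append(Signal(s.samples * k, s.sample_rate, s.label))
    return out, factors
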