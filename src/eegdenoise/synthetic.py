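"""Seeded generators of EEG-like and artifact-like segments.

Real clean-EEG and artifact pools come from public repositories; these
generators emulate their spectral structure so the whole pipeline is
testable without downloads:

* EEG: 1/f^alpha background plus alpha-band (8-13 Hz) and theta-band
  (4-8 Hz) oscillations with random amplitude and phase.
* EMG: broadband noise with an approximately flat power spectrum up to
  Nyquist (muscle activity has a relatively uniform energy distribution).
* EOG: smooth blink deflections plus slow drift, band-limited to
  0.5-5 Hz (the recording convention for ocular channels).
* ECG: a quasi-periodic QRS-like spike train at 50-90 bpm with a small
  T wave; spectral power concentrated below 20 Hz.

Band-limiting is done by frequency-domain masking with a smooth
(raised-cosine) rolloff rather than IIR filtering, so output is exactly
reproducible across platforms.  All generators emit zero-mean,
unit-variance segments; absolute amplitude is irrelevant downstream
because the contamination scale λ absorbs it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import (
    DEFAULT_DURATION_S,
    DEFAULT_FS,
    ConfigurationError,
    Segment,
    SegmentLabel,
    SegmentStore,
)

__all__ = ["GenSpec", "gen_eeg", "gen_emg", "gen_eog", "gen_ecg", "generate"]


@dataclass
class GenSpec:
    """Parameters shared by all segment generators.

    ``params`` carries type-specific knobs; unspecified entries fall back
    to the defaults documented in each generator.
    """

    n_segments: int = 1
    fs: float = DEFAULT_FS
    duration_s: float = DEFAULT_DURATION_S
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ConfigurationError("n_segments must be >= 1")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"duration_s * fs must be integral, got {n}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _finalize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization of one segment."""
    x = x - x.mean()
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x


def _smooth_band_mask(freqs: np.ndarray, lo: float, hi: float, roll: float) -> np.ndarray:
    """Raised-cosine band mask: 1 inside [lo, hi], cosine rolloff of width
    ``roll`` on each side, 0 beyond."""
    mask = np.zeros_like(freqs)
    inside = (freqs >= lo) & (freqs <= hi)
    mask[inside] = 1.0
    lo_edge = (freqs >= lo - roll) & (freqs < lo)
    mask[lo_edge] = 0.5 * (1 + np.cos(np.pi * (lo - freqs[lo_edge]) / roll))
    hi_edge = (freqs > hi) & (freqs <= hi + roll)
    mask[hi_edge] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_edge] - hi) / roll))
    return mask


def _colored_noise(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^alpha (random phases)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    return np.fft.irfft(spec, n=n)


def _band_oscillation(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Narrowband oscillation: a sinusoid with slowly wandering frequency
    inside [lo, hi] and random phase."""
    t = np.arange(n) / fs
    f0 = rng.uniform(lo, hi)
    phase = rng.uniform(0, 2 * np.pi)
    # slight frequency modulation keeps the band occupied without leaving it
    fm = 0.1 * (hi - lo) * np.sin(2 * np.pi * rng.uniform(0.1, 0.5) * t)
    x = np.sin(2 * np.pi * (f0 + fm) * t + phase)
    return x


def gen_eeg(spec: GenSpec) -> SegmentStore:
    """Clean-EEG-like segments: 1/f^alpha background + alpha/theta rhythms.

    Type-specific params: ``alpha_range`` (spectral exponent, default
    (1.0, 2.0)), ``alpha_band_amp`` (default 1.0), ``theta_band_amp``
    (default 0.6), relative to the unit-std background.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    a_lo, a_hi = p.get("alpha_range", (1.0, 2.0))
    alpha_amp = p.get("alpha_band_amp", 1.0)
    theta_amp = p.get("theta_band_amp", 0.6)
    n, fs = spec.n_samples, spec.fs
    rows = []
    for _ in range(spec.n_segments):
        bg = _colored_noise(rng, n, fs, rng.uniform(a_lo, a_hi))
        bg /= bg.std()
        x = (
            bg
            + alpha_amp * rng.uniform(0.5, 1.5) * _band_oscillation(rng, n, fs, 8.0, 13.0)
            + theta_amp * rng.uniform(0.5, 1.5) * _band_oscillation(rng, n, fs, 4.0, 8.0)
        )
        rows.append(_finalize(x))
    return SegmentStore.from_array(
        np.stack(rows), fs=fs, label=SegmentLabel.EEG,
        meta={"source": "synthetic-eeg", "seed": spec.seed},
    )


def gen_emg(spec: GenSpec) -> SegmentStore:
    """Muscle-artifact-like segments: broadband noise, near-flat PSD.

    Type-specific params: ``bandwidth_hz`` — upper edge of the flat band
    (default Nyquist).
    """
    rng = np.random.default_rng(spec.seed)
    n, fs = spec.n_samples, spec.fs
    hi = spec.params.get("bandwidth_hz", fs / 2)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = _smooth_band_mask(freqs, 0.0, hi, roll=max(1.0, 0.02 * hi))
    rows = []
    for _ in range(spec.n_segments):
        white = rng.standard_normal(n)
        x = np.fft.irfft(np.fft.rfft(white) * mask, n=n)
        rows.append(_finalize(x))
    return SegmentStore.from_array(
        np.stack(rows), fs=fs, label=SegmentLabel.EMG,
        meta={"source": "synthetic-emg", "seed": spec.seed},
    )


def gen_eog(spec: GenSpec) -> SegmentStore:
    """Ocular-artifact-like segments: blink bumps + drift, 0.5-5 Hz band.

    Type-specific params: ``blink_rate_hz`` (expected blinks per second,
    default 0.75), ``blink_width_s`` (FWHM-ish width, default 0.25).
    At least one blink is always placed, so the positive peak dominates
    the slow background.
    """
    rng = np.random.default_rng(spec.seed)
    n, fs = spec.n_samples, spec.fs
    p = spec.params
    rate = p.get("blink_rate_hz", 0.5)
    width = p.get("blink_width_s", 0.2)
    t = np.arange(n) / fs
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = _smooth_band_mask(freqs, 0.5, 5.0, roll=0.4)
    rows = []
    for _ in range(spec.n_segments):
        # slow drift background, then blinks an order of magnitude taller
        drift = _colored_noise(rng, n, fs, 2.5)
        drift /= drift.std()
        x = 0.25 * drift
        # well-separated blinks so each keeps a sharp positive peak
        n_blinks = min(2, max(1, rng.poisson(rate * spec.duration_s)))
        centers = []
        for _b in range(n_blinks):
            for _try in range(20):
                c = rng.uniform(0.15, spec.duration_s - 0.15)
                if all(abs(c - c0) > 0.5 for c0 in centers):
                    centers.append(c)
                    break
        for c in centers:
            w = width * rng.uniform(0.8, 1.2)
            amp = rng.uniform(4.0, 6.0)
            x = x + amp * np.exp(-0.5 * ((t - c) / (w / 2.355)) ** 2)
        x = np.fft.irfft(np.fft.rfft(x) * mask, n=n)
        rows.append(_finalize(x))
    return SegmentStore.from_array(
        np.stack(rows), fs=fs, label=SegmentLabel.EOG,
        meta={"source": "synthetic-eog", "seed": spec.seed},
    )


def _qrs_template(fs: float, width_s: float = 0.08) -> np.ndarray:
    """Biphasic QRS-like spike: second derivative of a Gaussian."""
    half = int(round(3 * width_s * fs))
    t = np.arange(-half, half + 1) / fs
    s = width_s / 2.0
    u = t / s
    return (1 - u**2) * np.exp(-0.5 * u**2)


def gen_ecg(spec: GenSpec) -> SegmentStore:
    """Cardiac-artifact-like segments: quasi-periodic QRS train + T waves.

    Type-specific params: ``bpm_range`` (default (50, 90)), ``jitter_cv``
    (coefficient of variation of inter-beat intervals, default 0.05 —
    well under the 0.2 regularity bound), ``t_wave_amp`` (default 0.3).
    """
    rng = np.random.default_rng(spec.seed)
    n, fs = spec.n_samples, spec.fs
    p = spec.params
    bpm_lo, bpm_hi = p.get("bpm_range", (50.0, 90.0))
    jitter_cv = p.get("jitter_cv", 0.05)
    t_amp = p.get("t_wave_amp", 0.3)
    qrs = _qrs_template(fs)
    t_wave = np.exp(-0.5 * ((np.arange(-int(0.12 * fs), int(0.12 * fs) + 1) / fs) / 0.05) ** 2)
    rows = []
    for _ in range(spec.n_segments):
        bpm = rng.uniform(bpm_lo, bpm_hi)
        period = 60.0 / bpm
        x = np.zeros(n)
        beat_t = rng.uniform(0, period)
        while beat_t < spec.duration_s:
            i0 = int(round(beat_t * fs))
            for tpl, off, amp in (
                (qrs, 0, 1.0),
                (t_wave, int(0.25 * fs), t_amp),
            ):
                a = i0 + off - len(tpl) // 2
                b = a + len(tpl)
                sa, sb = max(a, 0), min(b, n)
                if sa < sb:
                    x[sa:sb] += amp * tpl[sa - a : sb - a]
            beat_t += period * max(0.5, 1.0 + jitter_cv * rng.standard_normal())
        rows.append(_finalize(x))
    return SegmentStore.from_array(
        np.stack(rows), fs=fs, label=SegmentLabel.ECG,
        meta={"source": "synthetic-ecg", "seed": spec.seed},
    )


_GENERATORS = {
    "eeg": gen_eeg,
    "emg": gen_emg,
    "eog": gen_eog,
    "ecg": gen_ecg,
}


def generate(kind: str, spec: GenSpec) -> SegmentStore:
    """Dispatch to a generator by name ('eeg', 'emg', 'eog', 'ecg')."""
    try:
        fn = _GENERATORS[kind.lower()]
    except KeyError:
        raise ConfigurationError(f"unknown signal kind {kind!r}") from None
    return fn(spec)
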