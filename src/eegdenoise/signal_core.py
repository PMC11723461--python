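"""Fundamental segment containers and signal primitives.

A :class:`Segment` is a single-channel, fixed-length window of an
electrophysiological recording (by default 2 s at 512 Hz, i.e. 1024
samples).  Everything downstream — contamination, the network, the
evaluation metrics — operates on segments or homogeneous collections of
them (:class:`SegmentStore`).

Stores are persisted as a plain ``.npy`` 2-D array (segments x samples)
next to a JSON sidecar carrying the sampling rate, label and provenance
metadata, so a store is self-describing and round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.signal import periodogram as _scipy_periodogram

__all__ = [
    "SegmentLabel",
    "Segment",
    "SegmentStore",
    "rms",
    "periodogram_psd",
    "standardize",
    "read_store",
    "write_store",
    "InvalidInputError",
    "DegenerateInputError",
    "FormatError",
    "ConfigurationError",
]

DEFAULT_FS = 512.0
DEFAULT_DURATION_S = 2.0


class InvalidInputError(ValueError):
    """Raised when a segment violates a precondition (empty, non-finite, shape)."""


class DegenerateInputError(ValueError):
    """Raised for inputs that are valid in shape but degenerate in value
    (zero variance, zero RMS, uncontaminated baseline)."""


class FormatError(ValueError):
    """Raised when an on-disk store is inconsistent; names the offending field."""


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent (bad fractions,
    indivisible partition counts, missing components)."""


class SegmentLabel(str, Enum):
    EEG = "EEG"
    EMG = "EMG"
    EOG = "EOG"
    ECG = "ECG"
    MIXED = "MIXED"
    DENOISED = "DENOISED"


@dataclass
class Segment:
    """One single-channel window of signal.

    Parameters
    ----------
    samples
        1-D array of amplitudes (µV, or unitless after standardization).
    fs
        Sampling rate in Hz, > 0.
    label
        Signal class of the segment.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    label: SegmentLabel = SegmentLabel.EEG

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InvalidInputError("segment must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidInputError("segment contains non-finite samples")
        if not (self.fs > 0):
            raise InvalidInputError(f"sampling rate must be > 0, got {self.fs}")
        self.label = SegmentLabel(self.label)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def copy(self, **overrides) -> "Segment":
        kw = dict(samples=self.samples.copy(), fs=self.fs, label=self.label)
        kw.update(overrides)
        return Segment(**kw)


@dataclass
class SegmentStore:
    """Homogeneous, ordered collection of segments sharing fs and length."""

    segments: list[Segment] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_homogeneous()

    def _check_homogeneous(self) -> None:
        if not self.segments:
            return
        fs0, n0 = self.segments[0].fs, len(self.segments[0])
        for i, seg in enumerate(self.segments):
            if seg.fs != fs0:
                raise FormatError(f"segment {i}: fs {seg.fs} != {fs0} (field 'fs')")
            if len(seg) != n0:
                raise FormatError(
                    f"segment {i}: length {len(seg)} != {n0} (field 'length')"
                )

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]

    @property
    def fs(self) -> float:
        if not self.segments:
            raise InvalidInputError("empty store has no sampling rate")
        return self.segments[0].fs

    def as_array(self) -> np.ndarray:
        """(n_segments, n_samples) float64 matrix of all samples."""
        return np.stack([s.samples for s in self.segments])

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        fs: float = DEFAULT_FS,
        label: SegmentLabel = SegmentLabel.EEG,
        meta: dict | None = None,
    ) -> "SegmentStore":
        arr = np.atleast_2d(np.asarray(arr, dtype=np.float64))
        segs = [Segment(row, fs=fs, label=label) for row in arr]
        return cls(segs, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def rms(g: Segment | np.ndarray) -> float:
    """Root-mean-square amplitude, sqrt(mean(g_i^2)).

    Zero iff every sample is zero.  Absolutely homogeneous:
    ``rms(a*g) == |a| * rms(g)``.
    """
    x = g.samples if isinstance(g, Segment) else np.asarray(g, dtype=np.float64)
    if x.size == 0:
        raise InvalidInputError("rms of an empty segment is undefined")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("rms requires finite samples")
    return float(np.sqrt(np.mean(np.square(x))))


def periodogram_psd(g: Segment | np.ndarray, fs: float | None = None) -> np.ndarray:
    """One-sided periodogram PSD of a full segment.

    Single rectangular (boxcar) window over the whole segment, no
    averaging or overlap, density scaling; frequency resolution fs/N.
    Returns the PSD vector (power per Hz per bin); bin k corresponds to
    frequency k*fs/N for k = 0..N//2.
    """
    if isinstance(g, Segment):
        x, fs = g.samples, g.fs
    else:
        x = np.asarray(g, dtype=np.float64)
        fs = DEFAULT_FS if fs is None else fs
    if x.size == 0:
        raise InvalidInputError("periodogram of an empty segment is undefined")
    _, psd = _scipy_periodogram(
        x, fs=fs, window="boxcar", detrend=False, scaling="density"
    )
    return psd


def psd_frequencies(n: int, fs: float = DEFAULT_FS) -> np.ndarray:
    """Frequency axis matching :func:`periodogram_psd` for an n-sample segment."""
    return np.fft.rfftfreq(n, d=1.0 / fs)


def standardize(
    y: Segment, reference_scale: float | None = None
) -> tuple[Segment, float]:
    """Divide a segment by a positive scale, returning (scaled segment, scale).

    The scale defaults to the segment's own standard deviation, so the
    output has unit std; passing ``reference_scale`` applies a shared
    factor (used to keep a contaminated/clean/artifact triple on a common
    scale).  Multiplying back by the returned scale restores the input.
    """
    if reference_scale is not None:
        if not (reference_scale > 0):
            raise InvalidInputError(
                f"reference_scale must be > 0, got {reference_scale}"
            )
        scale = float(reference_scale)
    else:
        scale = float(np.std(y.samples))
        if scale == 0.0:
            raise DegenerateInputError(
                "zero-variance segment cannot be standardized by its own std"
            )
    return y.copy(samples=y.samples / scale), scale


# ---------------------------------------------------------------------------
# Container I/O: <name>.npy + <name>.json sidecar
# ---------------------------------------------------------------------------

def write_store(store: SegmentStore, path: str | Path) -> Path:
    """Write a store as ``<path>.npy`` (segments x samples) + ``<path>.json``.

    ``path`` may be given with or without the ``.npy`` suffix.
    """
    path = Path(path)
    if path.suffix == ".npy":
        path = path.with_suffix("")
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = store.as_array()
    np.save(path.with_suffix(".npy"), arr)
    sidecar = {
        "fs": store.fs if len(store) else DEFAULT_FS,
        "n_segments": len(store),
        "n_samples": int(arr.shape[1]) if len(store) else 0,
        "labels": [s.label.value for s in store.segments],
        "meta": store.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npy")


def read_store(path: str | Path) -> SegmentStore:
    """Read a store written by :func:`write_store`, validating the sidecar."""
    path = Path(path)
    if path.suffix == ".npy":
        path = path.with_suffix("")
    npy, sidecar = path.with_suffix(".npy"), path.with_suffix(".json")
    if not npy.exists():
        raise FormatError(f"missing array file {npy} (field 'samples')")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar} (field 'sidecar')")
    info = json.loads(sidecar.read_text())
    for key in ("fs", "n_segments", "n_samples", "labels"):
        if key not in info:
            raise FormatError(f"sidecar missing field '{key}'")
    arr = np.load(npy)
    if arr.ndim != 2:
        raise FormatError(f"array must be 2-D, got ndim={arr.ndim} (field 'samples')")
    if arr.shape[0] != info["n_segments"]:
        raise FormatError(
            f"array has {arr.shape[0]} segments, sidecar says "
            f"{info['n_segments']} (field 'n_segments')"
        )
    if info["n_segments"] and arr.shape[1] != info["n_samples"]:
        raise FormatError(
            f"array has {arr.shape[1]} samples, sidecar says "
            f"{info['n_samples']} (field 'n_samples')"
        )
    if len(info["labels"]) != arr.shape[0]:
        raise FormatError("label count mismatch (field 'labels')")
    segs = [
        Segment(row, fs=float(info["fs"]), label=SegmentLabel(lab))
        for row, lab in zip(arr, info["labels"])
    ]
    return SegmentStore(segs, meta=dict(info.get("meta", {})))
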