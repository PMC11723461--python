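"""Semi-simulated contamination: SNR-controlled mixing and data splits.

A contaminated segment is built by linear superposition

    y = x + λ·n

where x is clean EEG, n an artifact segment, and the scale λ sets the
nominal signal-to-noise ratio

    SNR = 10·log10( RMS(x) / RMS(λ·n) )   [dB].

Solving for λ gives λ = RMS(x) / (RMS(n)·10^(SNR/10)), so a requested
SNR is realized exactly.  Note the convention is the ratio of RMS
amplitudes (not powers) inside the log; under it the identity "denoiser"
f(y)=y has time-domain relative error RMS(y-x)/RMS(x) = 10^(-SNR/10),
exactly 1 at 0 dB — a useful analytic anchor for the metric suite.

The split protocol: 80/10/10 train/validation/test partition of
(clean, artifact) pairs, disjoint at the segment level.  Training pairs
are mixed at one SNR each drawn from -7..2 dB; every validation/test
pair is mixed once at each of the ten integer levels -7..2 dB, so those
partitions are 10x larger than their pair counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_core import (
    ConfigurationError,
    DegenerateInputError,
    InvalidInputError,
    Segment,
    SegmentLabel,
    SegmentStore,
    rms,
)

__all__ = [
    "ContaminatedPair",
    "SplitSpec",
    "Splits",
    "solve_lambda",
    "realized_snr_db",
    "mix",
    "make_mixed_pool",
    "build_splits",
]

EVAL_SNR_LEVELS_DB = tuple(range(-7, 3))  # -7 .. 2 dB inclusive


@dataclass
class ContaminatedPair:
    """One (clean, artifact, mixture) training/evaluation example."""

    x: Segment
    n: Segment
    lam: float
    y: Segment
    snr_db: float
    artifact_type: SegmentLabel

    def noise_component(self) -> np.ndarray:
        """The additive contamination λ·n (the branch-2 regression target)."""
        return self.lam * self.n.samples


@dataclass
class SplitSpec:
    """Configuration of the contamination + split protocol."""

    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    train_snr_range_db: tuple[float, float] = (-7.0, 2.0)
    eval_snr_levels_db: tuple[float, ...] = EVAL_SNR_LEVELS_DB
    seed: int = 0
    # 'integer-grid': train SNRs drawn uniformly from the ten integer levels;
    # 'continuous-uniform': drawn uniformly from the closed range.
    train_snr_mode: str = "integer-grid"

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"split fractions must sum to 1, got {total}")
        if self.train_snr_mode not in ("integer-grid", "continuous-uniform"):
            raise ConfigurationError(
                f"unknown train_snr_mode {self.train_snr_mode!r}"
            )


@dataclass
class Splits:
    train: list[ContaminatedPair] = field(default_factory=list)
    val: list[ContaminatedPair] = field(default_factory=list)
    test: list[ContaminatedPair] = field(default_factory=list)

    def manifest(self) -> dict:
        """JSON-serializable record of λ and SNR per pair in each partition."""
        return {
            part: [
                {
                    "lam": p.lam,
                    "snr_db": p.snr_db,
                    "artifact_type": p.artifact_type.value,
                }
                for p in getattr(self, part)
            ]
            for part in ("train", "val", "test")
        }


def solve_lambda(x: Segment, n: Segment, snr_db: float) -> float:
    """Scale λ that realizes the requested SNR for the mixture x + λ·n."""
    rx, rn = rms(x), rms(n)
    if rx == 0.0:
        raise DegenerateInputError("clean segment has zero RMS")
    if rn == 0.0:
        raise DegenerateInputError("artifact segment has zero RMS")
    return rx / (rn * 10.0 ** (snr_db / 10.0))


def realized_snr_db(x: Segment, n: Segment, lam: float) -> float:
    """SNR in dB of the mixture x + λ·n, 10·log10(RMS(x)/RMS(λ·n)).

    +inf for an uncontaminated mixture (λ=0), −inf for a silent clean
    component."""
    rx = rms(x)
    if lam == 0.0:
        return np.inf
    if rx == 0.0:
        return -np.inf
    return 10.0 * np.log10(rx / (abs(lam) * rms(n)))


def mix(x: Segment, n: Segment, lam: float) -> ContaminatedPair:
    """Linear superposition y = x + λ·n, keeping all components."""
    if len(x) != len(n):
        raise InvalidInputError(
            f"clean/artifact length mismatch: {len(x)} vs {len(n)}"
        )
    if x.fs != n.fs:
        raise InvalidInputError(f"clean/artifact fs mismatch: {x.fs} vs {n.fs}")
    y = Segment(x.samples + lam * n.samples, fs=x.fs, label=SegmentLabel.MIXED)
    snr = realized_snr_db(x, n, lam) if lam != 0 else np.inf
    return ContaminatedPair(
        x=x, n=n, lam=float(lam), y=y, snr_db=float(snr), artifact_type=n.label
    )


def make_mixed_pool(eog: SegmentStore, emg: SegmentStore) -> SegmentStore:
    """Mixed (EOG + EMG) artifact pool: sample-wise sum with equal unit
    weights; the single λ applied later scales the sum to the target SNR."""
    k = min(len(eog), len(emg))
    if k == 0:
        raise ConfigurationError("empty artifact pool for mixed contamination")
    arr = eog.as_array()[:k] + emg.as_array()[:k]
    return SegmentStore.from_array(
        arr, fs=eog.fs, label=SegmentLabel.MIXED,
        meta={"source": "mixed(eog+emg)"},
    )


def _pair_at(x: Segment, n: Segment, snr_db: float) -> ContaminatedPair:
    lam = solve_lambda(x, n, snr_db)
    pair = mix(x, n, lam)
    pair.snr_db = float(snr_db)  # nominal == realized by construction
    return pair


def build_splits(
    eeg_pool: SegmentStore, artifact_pool: SegmentStore, spec: SplitSpec
) -> Splits:
    """Pair clean and artifact segments, partition 80/10/10, and mix.

    Pairing is uniform-random without replacement under ``spec.seed``.
    Train pairs get one SNR each from the training range; each val/test
    pair is mixed once at every evaluation level, so those partitions
    hold ``n_pairs x n_levels`` examples.  The three partitions are
    disjoint at the segment level.
    """
    if len(eeg_pool) == 0 or len(artifact_pool) == 0:
        raise ConfigurationError("empty input pool")
    n_pairs = min(len(eeg_pool), len(artifact_pool))
    rng = np.random.default_rng(spec.seed)
    eeg_idx = rng.permutation(len(eeg_pool))[:n_pairs]
    art_idx = rng.permutation(len(artifact_pool))[:n_pairs]

    n_train = int(round(spec.train_frac * n_pairs))
    n_val = int(round(spec.val_frac * n_pairs))
    n_test = n_pairs - n_train - n_val
    if min(n_train, n_val, n_test) <= 0:
        raise ConfigurationError(
            f"split of {n_pairs} pairs leaves an empty partition "
            f"(train={n_train}, val={n_val}, test={n_test})"
        )

    lo, hi = spec.train_snr_range_db
    splits = Splits()
    for k in range(n_pairs):
        x, n = eeg_pool[eeg_idx[k]], artifact_pool[art_idx[k]]
        if k < n_train:
            if spec.train_snr_mode == "integer-grid":
                snr = float(rng.choice(spec.eval_snr_levels_db))
            else:
                snr = float(rng.uniform(lo, hi))
            splits.train.append(_pair_at(x, n, snr))
        else:
            dest = splits.val if k < n_train + n_val else splits.test
            for snr in spec.eval_snr_levels_db:
                dest.append(_pair_at(x, n, float(snr)))
    return splits
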