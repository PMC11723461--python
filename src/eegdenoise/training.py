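"""Alternating adversarial training with early stopping, plus inference.

One training step updates the three discriminators in turn on their own
least-squares losses (generator frozen), then updates the generator on
Ltotal (discriminators frozen).  After every epoch the generator's
plain MSE on the validation set (fused output vs clean target) is
computed; when it worsens more than C consecutive epochs training stops
and the best-validation checkpoint — not the last — is returned.

Inputs are standardized per pair: the contaminated segment is divided
by its own standard deviation and the same factor is applied to its
clean target and noise component, so the network always sees
unit-scale mixtures and the transform inverts exactly at test time.

Optimizer: Adam with (β1, β2) = (0.5, 0.9) for the generator and
(0.9, 0.999) for the discriminators, batch size 40, up to 1000 epochs.
The default learning rate is 1e-4; 1e-3 is the documented alternative
for short desk-scale runs where few updates are available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor, no_grad
from .contamination import ContaminatedPair
from .discriminator import Discriminator, DiscriminatorConfig
from .generator import DualBranchGenerator, GeneratorConfig
from .losses import LossReport, LossWeights, branch_losses, discriminator_loss
from .metrics import MetricReport, aggregate, pair_metrics
from .signal_core import (
    ConfigurationError,
    Segment,
    SegmentLabel,
    SegmentStore,
)

__all__ = [
    "TrainConfig",
    "Models",
    "TrainingDivergenceError",
    "build_models",
    "pairs_to_arrays",
    "train_step",
    "fit",
    "FitResult",
    "denoise",
    "denoise_array",
    "evaluate",
    "evaluate_with",
    "save_checkpoint",
    "load_checkpoint",
]


class TrainingDivergenceError(RuntimeError):
    """Raised when a loss goes non-finite; carries the epoch and step."""

    def __init__(self, message: str, epoch: int | None = None,
                 step: int | None = None):
        super().__init__(message)
        self.epoch, self.step = epoch, step


@dataclass
class TrainConfig:
    batch_size: int = 40
    max_epochs: int = 1000
    gen_adam: tuple[float, float] = (0.5, 0.9)
    disc_adam: tuple[float, float] = (0.9, 0.999)
    lr_gen: float = 1e-4
    lr_disc: float = 1e-4
    early_stop_C: int = 5
    inner_K: int = 1
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        for b in (*self.gen_adam, *self.disc_adam):
            if not (0.0 < b < 1.0):
                raise ConfigurationError(f"Adam beta {b} outside (0, 1)")
        if self.early_stop_C < 1 or self.inner_K < 1:
            raise ConfigurationError("early_stop_C and inner_K must be >= 1")


@dataclass
class Models:
    gen: DualBranchGenerator
    d1: Discriminator
    d2: Discriminator
    d3: Discriminator

    @property
    def discs(self) -> tuple[Discriminator, Discriminator, Discriminator]:
        return (self.d1, self.d2, self.d3)


def build_models(gen_cfg: GeneratorConfig,
                 disc_cfg: DiscriminatorConfig | None = None) -> Models:
    """Instantiate generator + three discriminators.

    The discriminators share architecture but never weights: each gets
    its own seed derived from the base seed."""
    if disc_cfg is None:
        disc_cfg = DiscriminatorConfig(
            width_scale=gen_cfg.width_scale, input_len=gen_cfg.input_len,
            seed=gen_cfg.seed,
        )
    discs = [
        Discriminator(
            DiscriminatorConfig(**{**disc_cfg.to_dict(),
                                   "seed": disc_cfg.seed + 1 + i})
        )
        for i in range(3)
    ]
    return Models(DualBranchGenerator(gen_cfg), *discs)


def pairs_to_arrays(
    pairs: list[ContaminatedPair],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack a pair list into standardized float32 (Y, X, N, scales).

    Each triple (y, x, λ·n) is divided by std(y); scales recover the
    original amplitudes."""
    ys = np.stack([p.y.samples for p in pairs])
    xs = np.stack([p.x.samples for p in pairs])
    ns = np.stack([p.noise_component() for p in pairs])
    scales = ys.std(axis=1)
    if np.any(scales == 0):
        raise ConfigurationError("zero-variance contaminated segment in batch")
    s = scales[:, None]
    return (
        (ys / s).astype(np.float32),
        (xs / s).astype(np.float32),
        (ns / s).astype(np.float32),
        scales,
    )


@dataclass
class Optimizers:
    gen: Adam
    d: tuple[Adam, Adam, Adam]


def build_optimizers(models: Models, cfg: TrainConfig) -> Optimizers:
    return Optimizers(
        gen=Adam(models.gen.parameters(), lr=cfg.lr_gen, betas=cfg.gen_adam),
        d=tuple(
            Adam(d.parameters(), lr=cfg.lr_disc, betas=cfg.disc_adam)
            for d in models.discs
        ),
    )


def train_step(
    batch: tuple[np.ndarray, np.ndarray, np.ndarray],
    models: Models,
    opts: Optimizers,
    cfg: TrainConfig,
    epoch: int | None = None,
    step: int | None = None,
) -> LossReport:
    """One alternating update on a standardized (Y, X, N) batch.

    D1, D2, D3 are each updated on their own loss with the generator's
    outputs detached, then the generator is updated on Ltotal with the
    discriminators frozen (eval mode)."""
    y, x, n = batch
    gen = models.gen
    gen.train()
    outputs = gen(y)
    fakes = (outputs.y1.data, outputs.y2.data, outputs.ypre.data)
    reals = (x, n, x)
    report_ld = {}
    for k, (disc, opt, fake, real) in enumerate(
        zip(models.discs, opts.d, fakes, reals), start=1
    ):
        disc.train()
        opt.zero_grad()
        ld = discriminator_loss(real, fake, disc)
        if not np.isfinite(ld.data):
            raise TrainingDivergenceError(
                f"discriminator {k} loss non-finite", epoch=epoch, step=step
            )
        ld.backward()
        opt.step()
        report_ld[k] = float(ld.data)
    for disc in models.discs:
        disc.eval()
    opts.gen.zero_grad()
    ltotal, report = branch_losses(outputs, x, n, models.discs, cfg.weights)
    if not np.isfinite(ltotal.data):
        raise TrainingDivergenceError(
            "generator loss non-finite", epoch=epoch, step=step
        )
    if cfg.lr_gen > 0:
        ltotal.backward()
        opts.gen.step()
    report.ld = report_ld
    return report


@dataclass
class FitResult:
    models: Models
    history: list[dict]
    best_epoch: int
    best_val_mse: float
    epochs_run: int


def _validation_mse(models: Models, val_arrays, chunk: int = 64) -> float:
    """Plain MSE of the fused output against the clean target (eval mode)."""
    y, x, _, _ = val_arrays
    gen = models.gen
    gen.eval()
    se, count = 0.0, 0
    with no_grad():
        for a in range(0, y.shape[0], chunk):
            ypre = gen(y[a : a + chunk]).ypre.data
            se += float(((ypre - x[a : a + chunk]) ** 2).sum())
            count += ypre.size
    gen.train()
    return se / count


def fit(
    train_pairs: list[ContaminatedPair],
    val_pairs: list[ContaminatedPair],
    models: Models,
    cfg: TrainConfig,
    log_path: str | Path | None = None,
    val_metric_fn=None,
) -> FitResult:
    """Run the alternating training loop with early stopping.

    Stops when the validation MSE has worsened more than ``early_stop_C``
    consecutive epochs (or at ``max_epochs``) and restores the weights of
    the best-validation epoch.  ``val_metric_fn(models, epoch) -> float``
    replaces the default validation MSE when given (used to construct
    specific early-stopping schedules in tests).  A JSONL row per epoch
    is appended to ``log_path`` when provided."""
    if not train_pairs or (not val_pairs and val_metric_fn is None):
        raise ConfigurationError("empty training or validation set")
    train_arrays = pairs_to_arrays(train_pairs)
    val_arrays = pairs_to_arrays(val_pairs) if val_pairs else None
    opts = build_optimizers(models, cfg)
    rng = np.random.default_rng(cfg.seed)
    n = train_arrays[0].shape[0]
    history: list[dict] = []
    best_val, best_epoch, best_state = np.inf, 0, None
    prev_val, worse_streak = np.inf, 0
    log_fh = open(log_path, "w") if log_path is not None else None
    try:
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            step_rows = []
            for s in range(0, n, cfg.batch_size):
                idx = order[s : s + cfg.batch_size]
                if idx.size < 2:
                    continue  # a single segment cannot batch-normalize
                batch = tuple(a[idx] for a in train_arrays[:3])
                for _ in range(cfg.inner_K):
                    report = train_step(batch, models, opts, cfg,
                                        epoch=epoch, step=s // cfg.batch_size)
                step_rows.append(report.row())
            epoch_row = {
                k: float(np.mean([r[k] for r in step_rows]))
                for k in step_rows[0]
            }
            if val_metric_fn is not None:
                val_mse = float(val_metric_fn(models, epoch))
            else:
                val_mse = _validation_mse(models, val_arrays)
            epoch_row = {"epoch": epoch, **epoch_row, "val_mse": val_mse}
            history.append(epoch_row)
            if log_fh is not None:
                log_fh.write(json.dumps(epoch_row) + "\n")
                log_fh.flush()
            if val_mse < best_val:
                best_val, best_epoch = val_mse, epoch
                best_state = [a.copy() for a in _models_state(models)]
            if val_mse > prev_val:
                worse_streak += 1
            else:
                worse_streak = 0
            prev_val = val_mse
            if worse_streak > cfg.early_stop_C:
                break
    finally:
        if log_fh is not None:
            log_fh.close()
    if best_state is not None:
        _models_load_state(models, best_state)
    models.gen.eval()
    return FitResult(models=models, history=history, best_epoch=best_epoch,
                     best_val_mse=best_val, epochs_run=len(history))


def _models_state(models: Models) -> list[np.ndarray]:
    out = []
    for m in (models.gen, *models.discs):
        out.extend(m.state_arrays())
    return out


def _models_load_state(models: Models, arrays: list[np.ndarray]) -> None:
    counts = [len(m.state_arrays()) for m in (models.gen, *models.discs)]
    pos = 0
    for m, c in zip((models.gen, *models.discs), counts):
        m.load_state_arrays(arrays[pos : pos + c])
        pos += c


# ---------------------------------------------------------------------------
# Inference and evaluation
# ---------------------------------------------------------------------------

def denoise_array(gen: DualBranchGenerator, y: np.ndarray,
                  chunk: int = 64) -> np.ndarray:
    """Denoise (B, L) raw-amplitude mixtures: standardize each row by its
    std, run the generator (eval mode), take the fused output, invert."""
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    scales = y.std(axis=1)
    if np.any(scales == 0):
        raise ConfigurationError("zero-variance segment cannot be denoised")
    ystd = (y / scales[:, None]).astype(np.float32)
    gen.eval()
    with no_grad():
        parts = [
            gen(ystd[a : a + chunk]).ypre.data
            for a in range(0, y.shape[0], chunk)
        ]
    out = np.concatenate(parts, axis=0).astype(np.float64)
    return out * scales[:, None]


def denoise(gen: DualBranchGenerator, store: SegmentStore) -> SegmentStore:
    """Denoise every segment of a store, preserving fs and length."""
    out = denoise_array(gen, store.as_array())
    return SegmentStore(
        [Segment(row, fs=store.fs, label=SegmentLabel.DENOISED) for row in out],
        meta={**store.meta, "denoised": True},
    )


def evaluate_with(denoise_fn, pairs: list[ContaminatedPair]) -> MetricReport:
    """Metric report for an arbitrary denoiser ``denoise_fn((B, L)) -> (B, L)``
    applied to the contaminated side of each pair."""
    ys = np.stack([p.y.samples for p in pairs])
    fys = denoise_fn(ys)
    records = [
        pair_metrics(fy, p.y.samples, p.x.samples, fs=p.x.fs,
                     snr_db=p.snr_db, artifact_type=p.artifact_type.value)
        for fy, p in zip(fys, pairs)
    ]
    return aggregate(records)


def evaluate(models: Models | DualBranchGenerator,
             pairs: list[ContaminatedPair]) -> MetricReport:
    """Six-metric report of the trained generator on evaluation pairs,
    aggregated per SNR level plus the grand mean."""
    gen = models.gen if isinstance(models, Models) else models
    return evaluate_with(lambda y: denoise_array(gen, y), pairs)


# ---------------------------------------------------------------------------
# Checkpoints: weights + configs + seed, self-describing
# ---------------------------------------------------------------------------

def save_checkpoint(models: Models, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for tag, m in zip(("gen", "d1", "d2", "d3"), (models.gen, *models.discs)):
        for i, a in enumerate(m.state_arrays()):
            arrays[f"{tag}_{i:04d}"] = a
    meta = json.dumps({
        "gen_cfg": models.gen.cfg.to_dict(),
        "disc_cfgs": [d.cfg.to_dict() for d in models.discs],
    })
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def load_checkpoint(path: str | Path) -> Models:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        gen = DualBranchGenerator(GeneratorConfig.from_dict(meta["gen_cfg"]))
        discs = [
            Discriminator(DiscriminatorConfig.from_dict(d))
            for d in meta["disc_cfgs"]
        ]
        models = Models(gen, *discs)
        for tag, m in zip(("gen", "d1", "d2", "d3"), (gen, *discs)):
            keys = sorted(k for k in z.files if k.startswith(tag + "_"))
            m.load_state_arrays([z[k] for k in keys])
    models.gen.eval()
    for d in models.discs:
        d.eval()
    return models
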