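"""The adversarial loss system binding generator outputs to discriminators.

Each of the three generator outputs carries its own composite loss

    Loss_k = L_mse + λ1·L_feat + λ2·L_adv,      k = 1, 2, 3

where L_mse is the regression error against the branch target, L_feat
the MSE between discriminator feature maps of prediction and target,
and L_adv the least-squares adversarial term mean((D(pred) − 1)²).
Branch 1 regresses on the clean signal x, branch 2 on the additive
contamination λ·n (so that Xraw − Y2 cancels the noise), and the fused
output again on x.  The generator minimizes Ltotal = Loss1+Loss2+Loss3.

Each discriminator minimizes the least-squares objective

    L_D = mean( ½·D(fake)² + ½·(D(real) − 1)² ).

The feature maps φ used by L_feat default to all 8 discriminator stages
(per-stage MSE averaged over stages); a single stage can be selected
instead."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .discriminator import Discriminator
from .generator import GeneratorOutputs
from .signal_core import ConfigurationError, InvalidInputError

__all__ = [
    "LossWeights",
    "LossReport",
    "mse_loss",
    "feature_loss",
    "adversarial_loss",
    "adversarial_loss_from_scores",
    "discriminator_loss",
    "discriminator_loss_from_scores",
    "branch_losses",
]


@dataclass
class LossWeights:
    """Weights of the feature (λ1) and adversarial (λ2) terms.

    The composite objective is dominated by the regression term; the
    defaults keep the auxiliary terms two orders of magnitude smaller.
    """

    lambda1: float = 0.01
    lambda2: float = 0.01
    # "all": per-stage MSE averaged over the 8 stages; an int selects one
    feature_stages: str | int = "all"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lambda1) and self.lambda1 >= 0):
            raise ConfigurationError(f"lambda1 must be finite >= 0: {self.lambda1}")
        if not (np.isfinite(self.lambda2) and self.lambda2 >= 0):
            raise ConfigurationError(f"lambda2 must be finite >= 0: {self.lambda2}")


@dataclass
class LossReport:
    """Scalar summary of one loss evaluation (floats, detached)."""

    branches: dict = field(default_factory=dict)  # {1: {mse, feat, adv, total}, ...}
    ltotal: float = 0.0
    ld: dict = field(default_factory=dict)        # {1: ld1, 2: ld2, 3: ld3}

    def row(self) -> dict:
        """Flat dict for CSV/JSONL logging."""
        out = {}
        for k, parts in sorted(self.branches.items()):
            for name, v in parts.items():
                out[f"loss{k}_{name}"] = v
        out["ltotal"] = self.ltotal
        for k, v in sorted(self.ld.items()):
            out[f"ld{k}"] = v
        return out


def _as_tensor(x) -> Tensor:
    # float64 passes through untouched so metric-grade precision is
    # available; everything else lands on the network's float32
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def mse_loss(pred, target) -> Tensor:
    """Per-sample MSE averaged over the batch (== global mean square error)."""
    pred, target = _as_tensor(pred), _as_tensor(target)
    if pred.shape != target.shape:
        raise InvalidInputError(f"shape mismatch {pred.shape} vs {target.shape}")
    return ((pred - target) ** 2.0).mean()


def feature_loss(pred, target, disc: Discriminator,
                 stages: str | int = "all") -> Tensor:
    """MSE between discriminator feature maps of prediction and target.

    The discriminator is used as a frozen feature extractor (callers put
    it in eval mode); with ``stages='all'`` the per-stage MSEs are
    averaged over the M stages, an integer selects a single stage."""
    fp = disc(_as_tensor(pred)).features
    with no_grad():
        ft = disc(_as_tensor(target)).features
    if isinstance(stages, int):
        pairs = [(fp[stages], ft[stages])]
    else:
        pairs = list(zip(fp, ft))
    total = None
    for a, b in pairs:
        term = ((a - b) ** 2.0).mean()
        total = term if total is None else total + term
    return total * (1.0 / len(pairs))


def adversarial_loss_from_scores(scores: Tensor) -> Tensor:
    """mean((score − 1)²) over the batch."""
    return ((scores - 1.0) ** 2.0).mean()


def adversarial_loss(pred, disc: Discriminator) -> Tensor:
    """Least-squares generator loss, mean((D(pred) − 1)²)."""
    return adversarial_loss_from_scores(disc(_as_tensor(pred)).score)


def discriminator_loss_from_scores(fake_scores: Tensor, real_scores: Tensor) -> Tensor:
    """mean(½·D(fake)² + ½·(D(real) − 1)²)."""
    return (0.5 * fake_scores**2.0 + 0.5 * (real_scores - 1.0) ** 2.0).mean()


def discriminator_loss(real, fake, disc: Discriminator) -> Tensor:
    """Least-squares discriminator objective on a (real, fake) batch pair."""
    return discriminator_loss_from_scores(disc(_as_tensor(fake)).score,
                                          disc(_as_tensor(real)).score)


def branch_losses(
    outputs: GeneratorOutputs,
    x,
    noise_target,
    discs: tuple[Discriminator, Discriminator, Discriminator],
    w: LossWeights,
) -> tuple[Tensor, LossReport]:
    """Composite generator loss over the three outputs.

    Branch 1: (y1 vs x, D1); branch 2: (y2 vs λ·n, D2); fused output:
    (ypre vs x, D3).  Returns the differentiable Ltotal and a detached
    scalar report satisfying total_k = mse_k + λ1·feat_k + λ2·adv_k and
    Ltotal = Loss1 + Loss2 + Loss3."""
    if discs is None or len(discs) != 3 or any(d is None for d in discs):
        raise ConfigurationError("branch_losses requires all three discriminators")
    x, noise_target = _as_tensor(x), _as_tensor(noise_target)
    d1, d2, d3 = discs
    report = LossReport()
    ltotal = None
    for k, (pred, target, disc) in enumerate(
        [(outputs.y1, x, d1), (outputs.y2, noise_target, d2),
         (outputs.ypre, x, d3)],
        start=1,
    ):
        mse = mse_loss(pred, target)
        feat = feature_loss(pred, target, disc, stages=w.feature_stages)
        adv = adversarial_loss(pred, disc)
        total = mse + w.lambda1 * feat + w.lambda2 * adv
        report.branches[k] = {
            "mse": float(mse.data), "feat": float(feat.data),
            "adv": float(adv.data), "total": float(total.data),
        }
        ltotal = total if ltotal is None else ltotal + total
    report.ltotal = float(ltotal.data)
    return ltotal, report
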