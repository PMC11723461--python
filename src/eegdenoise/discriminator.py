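"""Realism discriminators for the adversarial objective.

Three structurally identical discriminators are trained independently:
D1 scores branch-1 clean estimates against real clean EEG, D2 scores
branch-2 noise estimates against the true additive contamination, and
D3 scores the fused prediction against real clean EEG.

Each is a stack of M = 8 one-dimensional convolution layers (channels
64, 64, 128, 128, 256, 256, 512, 512; kernel 3, stride 2, padding 1),
each followed by batch normalization and a leaky-ReLU activation, so an
input of 1024 samples is halved to 4 time steps, then flattened through
one fully connected head to a single realism score per item.  The
post-activation feature map of every stage is returned alongside the
score; the feature loss compares these maps between real and generated
signals.  Following the least-squares adversarial objective, the score
has no sigmoid by default (a config flag restores one)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import BatchNorm1d, Conv1d, Linear, Module, Tensor
from .signal_core import ConfigurationError, InvalidInputError

__all__ = ["DiscriminatorConfig", "DiscriminatorOutputs", "Discriminator"]


@dataclass
class DiscriminatorConfig:
    channels: tuple[int, ...] = (64, 64, 128, 128, 256, 256, 512, 512)
    kernel: int = 3
    stride: int = 2
    padding: int = 1
    n_layers: int = 8
    lrelu_slope: float = 0.2
    width_scale: float = 1.0
    input_len: int = 1024
    sigmoid_head: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if len(self.channels) != self.n_layers:
            raise ConfigurationError(
                f"n_layers={self.n_layers} != len(channels)={len(self.channels)}"
            )
        if self.input_len % self.stride**self.n_layers:
            raise ConfigurationError(
                f"input_len {self.input_len} not divisible through "
                f"{self.n_layers} stride-{self.stride} stages"
            )

    def scaled(self, d: int) -> int:
        return max(1, int(round(d / self.width_scale)))

    def stage_lengths(self) -> list[int]:
        out, L = [], self.input_len
        for _ in range(self.n_layers):
            L = (L + 2 * self.padding - self.kernel) // self.stride + 1
            out.append(L)
        return out

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["channels"] = list(self.channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminatorConfig":
        d = dict(d)
        d["channels"] = tuple(d["channels"])
        return cls(**d)


@dataclass
class DiscriminatorOutputs:
    score: Tensor          # (B,) realism score per item
    features: list[Tensor]  # post-activation map of each of the M stages


class Discriminator(Module):
    def __init__(self, cfg: DiscriminatorConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.convs, self.bns = [], []
        prev = 1
        for c in cfg.channels:
            c = cfg.scaled(c)
            self.convs.append(
                Conv1d(prev, c, cfg.kernel, rng, stride=cfg.stride,
                       padding=cfg.padding, bias=False)
            )
            self.bns.append(BatchNorm1d(c))
            prev = c
        final_len = cfg.stage_lengths()[-1]
        self.head = Linear(prev * final_len, 1, rng)

    def forward(self, s: Tensor | np.ndarray) -> DiscriminatorOutputs:
        x = s if isinstance(s, Tensor) else Tensor(np.asarray(s, np.float32))
        if x.ndim != 2 or x.shape[1] != self.cfg.input_len:
            raise InvalidInputError(
                f"expected (batch, {self.cfg.input_len}), got {x.shape}"
            )
        B = x.shape[0]
        h = x.reshape(B, 1, self.cfg.input_len)
        features: list[Tensor] = []
        for conv, bn in zip(self.convs, self.bns):
            h = bn(conv(h)).leaky_relu(self.cfg.lrelu_slope)
            features.append(h)
        score = self.head(h.reshape(B, -1)).reshape(B)
        if self.cfg.sigmoid_head:
            score = score.sigmoid()
        return DiscriminatorOutputs(score=score, features=features)

    __call__ = forward
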