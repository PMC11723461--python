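"""Dual-branch generator with tanh-gated fusion.

The generator holds two structurally identical branches: branch 1 learns
the distribution of clean EEG and emits a clean-signal estimate Y1;
branch 2 learns the artifact distribution and emits a noise estimate Y2
(the additive contamination λ·n).  Two small gating networks map the raw
input to tanh masks, and the fused prediction is

    Ypre = mask1 ⊙ Y1 + mask2 ⊙ (Xraw − Y2)

so the model can blend the direct clean estimate with the
subtract-the-noise route, element by element.

Each branch runs: a preprocessing stage (two 1-D convolutions + average
pooling, lifting the signal to ``pre_dim`` channels over half the
samples), five encoding blocks with channel widths doubling 64→1024,
and a decoder (two convolutions + one fully connected layer) restoring
the original 1024 samples.  Every encoding block runs a CNN stream
(two conv/BN/LReLU layers) in parallel with a Local–Global Transformer
Block (LGTB): partition-local self-attention over 8 contiguous chunks,
a feedforward, global self-attention over all tokens, a second
feedforward — all residual — then a conv/BN/LReLU tail.  The two
streams stay independent until a single end-of-encoder fusion layer
(channel concat → 1×1 conv → BN).  Each block halves the token count,
so attention cost stays bounded and the decoder's fully connected layer
is small.

``width_scale`` divides every channel width uniformly, giving faithful
desk-scale models for testing (width_scale=8 turns 64..1024 into
8..128).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (
    Adam,
    BatchNorm1d,
    Conv1d,
    Linear,
    Module,
    MultiHeadSelfAttention,
    Tensor,
    concat,
)
from .signal_core import ConfigurationError, InvalidInputError

__all__ = ["GeneratorConfig", "GeneratorOutputs", "DualBranchGenerator", "fuse"]


@dataclass
class GeneratorConfig:
    input_len: int = 1024
    pre_dim: int = 32
    encoder_dims: tuple[int, ...] = (64, 128, 256, 512, 1024)
    n_blocks: int = 5
    local_partitions: int = 8
    conv_kernel: int = 3
    lrelu_slope: float = 0.2
    width_scale: float = 1.0
    gate_hidden: int = 512
    attn_heads: int = 4
    seed: int = 0
    # ablation switches
    clean_branch_only: bool = False
    noise_branch_only: bool = False
    no_transformer: bool = False
    plain_self_attention: bool = False

    def __post_init__(self) -> None:
        self.encoder_dims = tuple(self.encoder_dims)
        if self.n_blocks != len(self.encoder_dims):
            raise ConfigurationError(
                f"n_blocks={self.n_blocks} != len(encoder_dims)="
                f"{len(self.encoder_dims)}"
            )
        if self.clean_branch_only and self.noise_branch_only:
            raise ConfigurationError("at most one single-branch ablation flag")
        if self.input_len % 2**(self.n_blocks + 1):
            raise ConfigurationError(
                f"input_len {self.input_len} not divisible by "
                f"2^{self.n_blocks + 1}"
            )
        if self.latent_tokens % self.local_partitions:
            raise ConfigurationError(
                f"local_partitions={self.local_partitions} does not divide "
                f"the token count {self.latent_tokens} at the last block"
            )
        for d in (self.pre_dim, *self.encoder_dims):
            if self.scaled(d) < 1:
                raise ConfigurationError(f"width_scale leaves dim {d} < 1")
        for d in (self.pre_dim, *self.encoder_dims[:-1]):
            if self.scaled(d) % self.attn_heads:
                raise ConfigurationError(
                    f"scaled dim {self.scaled(d)} not divisible by "
                    f"attn_heads={self.attn_heads}"
                )

    def scaled(self, d: int) -> int:
        return max(1, int(round(d / self.width_scale)))

    @property
    def tokens(self) -> int:
        """Token count after preprocessing (average pooling by 2)."""
        return self.input_len // 2

    @property
    def latent_tokens(self) -> int:
        """Token count at the encoder output (each block halves it)."""
        return self.tokens // 2**self.n_blocks

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["encoder_dims"] = list(self.encoder_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["encoder_dims"] = tuple(d["encoder_dims"])
        return cls(**d)


@dataclass
class GeneratorOutputs:
    """The five signal-shaped tensors a forward pass produces."""

    y1: Tensor
    y2: Tensor
    mask1: Tensor
    mask2: Tensor
    ypre: Tensor


def fuse(xraw: Tensor, y1: Tensor, y2: Tensor, mask1: Tensor, mask2: Tensor) -> Tensor:
    """Gated fusion: mask1 ⊙ y1 + mask2 ⊙ (xraw − y2), elementwise."""
    shapes = {t.shape for t in (xraw, y1, y2, mask1, mask2)}
    if len(shapes) != 1:
        raise InvalidInputError(f"fuse: mismatched shapes {shapes}")
    return mask1 * y1 + mask2 * (xraw - y2)


class FeedForward(Module):
    """Residual position-wise feedforward on (B, T, C)."""

    def __init__(self, dim: int, rng: np.random.Generator, slope: float):
        super().__init__()
        self.fc1 = Linear(dim, dim, rng)
        self.fc2 = Linear(dim, dim, rng)
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.fc2(self.fc1(x).leaky_relu(self.slope))


class LocalGlobalTransformerBlock(Module):
    """Partition-local attention → FFN → global attention → FFN (residual),
    then a conv/BN/LReLU tail projecting to the block's channel width.

    With ``plain_attention`` the local/global pair collapses to a single
    full-sequence self-attention stage (the self-attention ablation)."""

    def __init__(self, in_dim: int, out_dim: int, partitions: int, heads: int,
                 kernel: int, slope: float, rng: np.random.Generator,
                 plain_attention: bool = False):
        super().__init__()
        self.partitions = partitions
        self.plain = plain_attention
        self.local_attn = None if plain_attention else MultiHeadSelfAttention(in_dim, heads, rng)
        self.ffn1 = None if plain_attention else FeedForward(in_dim, rng, slope)
        self.global_attn = MultiHeadSelfAttention(in_dim, heads, rng)
        self.ffn2 = FeedForward(in_dim, rng, slope)
        self.tail = Conv1d(in_dim, out_dim, kernel, rng, padding=kernel // 2, bias=False)
        self.bn = BatchNorm1d(out_dim)
        self.slope = slope

    def attention_stack(self, tokens: Tensor) -> Tensor:
        """The residual attention/feedforward stages on (B, T, C) tokens."""
        B, T, C = tokens.shape
        h = tokens
        if not self.plain:
            P = self.partitions
            if T % P:
                raise ConfigurationError(
                    f"token count {T} not divisible by partitions {P}"
                )
            chunks = h.reshape(B * P, T // P, C)
            h = h + self.local_attn(chunks).reshape(B, T, C)
            h = self.ffn1(h)
        h = h + self.global_attn(h)
        return self.ffn2(h)

    def __call__(self, x: Tensor) -> Tensor:
        """(B, C_in, T) → (B, C_out, T/2); pools then attends."""
        h = x.avg_pool1d(2)
        tokens = h.transpose(0, 2, 1)
        tokens = self.attention_stack(tokens)
        h = tokens.transpose(0, 2, 1)
        return self.bn(self.tail(h)).leaky_relu(self.slope)


class ConvBlock(Module):
    """Two conv/BN/LReLU layers; the first downsamples by stride 2."""

    def __init__(self, in_dim: int, out_dim: int, kernel: int, slope: float,
                 rng: np.random.Generator):
        super().__init__()
        p = kernel // 2
        self.conv1 = Conv1d(in_dim, out_dim, kernel, rng, stride=2, padding=p, bias=False)
        self.bn1 = BatchNorm1d(out_dim)
        self.conv2 = Conv1d(out_dim, out_dim, kernel, rng, padding=p, bias=False)
        self.bn2 = BatchNorm1d(out_dim)
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).leaky_relu(self.slope)
        return self.bn2(self.conv2(h)).leaky_relu(self.slope)


class BranchGenerator(Module):
    """One encoder–decoder branch: preprocess → 5 parallel CNN/LGTB blocks
    → fusion layer → decoder."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        k, p, slope = cfg.conv_kernel, cfg.conv_kernel // 2, cfg.lrelu_slope
        pre = cfg.scaled(cfg.pre_dim)
        self.pre_conv1 = Conv1d(1, pre, k, rng, padding=p)
        self.pre_conv2 = Conv1d(pre, pre, k, rng, padding=p)
        dims = [cfg.scaled(d) for d in cfg.encoder_dims]
        self.cnn_blocks = []
        self.lgtb_blocks = []
        prev = pre
        for d in dims:
            self.cnn_blocks.append(ConvBlock(prev, d, k, slope, rng))
            if not cfg.no_transformer:
                self.lgtb_blocks.append(
                    LocalGlobalTransformerBlock(
                        prev, d, cfg.local_partitions, cfg.attn_heads, k,
                        slope, rng, plain_attention=cfg.plain_self_attention,
                    )
                )
            prev = d
        fusion_in = dims[-1] * (1 if cfg.no_transformer else 2)
        self.fusion_conv = Conv1d(fusion_in, dims[-1], 1, rng, bias=False)
        self.fusion_bn = BatchNorm1d(dims[-1])
        self.dec_conv1 = Conv1d(dims[-1], pre * 4, k, rng, padding=p)
        self.dec_conv2 = Conv1d(pre * 4, pre * 2, k, rng, padding=p)
        self.dec_fc = Linear(pre * 2 * cfg.latent_tokens, cfg.input_len, rng)
        self.slope = slope

    def preprocess(self, x: Tensor) -> Tensor:
        """(B, input_len) → (B, pre_dim, input_len/2)."""
        B, L = x.shape
        if L != self.cfg.input_len:
            raise InvalidInputError(
                f"expected length {self.cfg.input_len}, got {L}"
            )
        h = x.reshape(B, 1, L)
        h = self.pre_conv1(h).leaky_relu(self.slope)
        h = self.pre_conv2(h).leaky_relu(self.slope)
        return h.avg_pool1d(2)

    def encode(self, h: Tensor) -> Tensor:
        """Parallel streams over 5 blocks, then the feature fusion layer."""
        hc = hl = h
        for i, cnn in enumerate(self.cnn_blocks):
            hc = cnn(hc)
            if not self.cfg.no_transformer:
                hl = self.lgtb_blocks[i](hl)
        if self.cfg.no_transformer:
            fused = hc
        else:
            if hc.shape != hl.shape:
                raise AssertionError(
                    f"stream shape mismatch: {hc.shape} vs {hl.shape}"
                )
            fused = concat([hc, hl], axis=1)
        return self.fusion_bn(self.fusion_conv(fused))

    def decode(self, z: Tensor) -> Tensor:
        """(B, C_latent, tokens) → (B, input_len)."""
        h = self.dec_conv1(z).leaky_relu(self.slope)
        h = self.dec_conv2(h).leaky_relu(self.slope)
        B = h.shape[0]
        return self.dec_fc(h.reshape(B, -1))

    def __call__(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(self.preprocess(x)))


class GatingNetwork(Module):
    """Two fully connected layers with a tanh output mask in (−1, 1).

    ``init_bias`` shifts the pre-tanh output at initialization: the
    noise-branch gate starts open (mask near +0.9) so the fusion begins
    close to the algebraically correct route Xraw − Y2, while the
    clean-branch gate starts neutral and opens as branch 1 earns it."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator,
                 init_bias: float = 0.0):
        super().__init__()
        hidden = cfg.scaled(cfg.gate_hidden)
        self.fc1 = Linear(cfg.input_len, hidden, rng)
        self.fc2 = Linear(hidden, cfg.input_len, rng)
        self.fc2.bias.data += np.float32(init_bias)
        self.slope = cfg.lrelu_slope

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).leaky_relu(self.slope)).tanh()


class DualBranchGenerator(Module):
    """The full generator: two branches + two gates + gated fusion."""

    def __init__(self, cfg: GeneratorConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.branch1 = None if cfg.noise_branch_only else BranchGenerator(cfg, rng)
        self.branch2 = None if cfg.clean_branch_only else BranchGenerator(cfg, rng)
        if not (cfg.clean_branch_only or cfg.noise_branch_only):
            self.gate1 = GatingNetwork(cfg, rng, init_bias=0.0)
            self.gate2 = GatingNetwork(cfg, rng, init_bias=1.5)
        else:
            self.gate1 = self.gate2 = None

    def forward(self, xraw: Tensor | np.ndarray) -> GeneratorOutputs:
        x = xraw if isinstance(xraw, Tensor) else Tensor(np.asarray(xraw, np.float32))
        if x.ndim != 2:
            raise InvalidInputError(f"expected (batch, samples), got {x.shape}")
        zeros = Tensor(np.zeros(x.shape, dtype=np.float32))
        ones = Tensor(np.ones(x.shape, dtype=np.float32))
        if self.cfg.clean_branch_only:
            y1 = self.branch1(x)
            return GeneratorOutputs(y1=y1, y2=zeros, mask1=ones, mask2=zeros,
                                    ypre=y1)
        if self.cfg.noise_branch_only:
            y2 = self.branch2(x)
            return GeneratorOutputs(y1=zeros, y2=y2, mask1=zeros, mask2=ones,
                                    ypre=x - y2)
        y1 = self.branch1(x)
        y2 = self.branch2(x)
        mask1 = self.gate1(x)
        mask2 = self.gate2(x)
        return GeneratorOutputs(
            y1=y1, y2=y2, mask1=mask1, mask2=mask2,
            ypre=fuse(x, y1, y2, mask1, mask2),
        )

    __call__ = forward
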