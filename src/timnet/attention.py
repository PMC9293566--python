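"""Dual channel/spatial attention bottleneck.

The block refines the deepest encoder map in two sequential steps, CBAM
style.  Channel attention squeezes each channel by global average and max
pooling, passes both pooled vectors through one shared two-layer MLP with a
reduction ratio ``r``, sums the branches and applies a logistic sigmoid:

    F_c = sigma( W1 relu(W0 avgpool(F)) + W1 relu(W0 maxpool(F)) )

Spatial attention pools across channels per pixel (mean and max), stacks
the two planes and runs a single 7x7 convolution (padding 3, so the spatial
size is preserved) followed by a sigmoid:

    F_s = sigma( f7x7([avgpool_c(F) ; maxpool_c(F)]) )

The full block first maps the encoder output G through a 1x1 convolution
(keeping the channel count), gates it by channel then by spatial attention
and adds a residual:

    F  = conv1x1(G)
    F' = F + (F * F_c(F)) * F_s(F * F_c(F))

Both attention maps lie strictly in (0, 1) for finite inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import grad as G
from .exceptions import ConfigurationError, ValidationError
from .grad import Tensor
from .nn import Conv2d, Module, Parameter, he_init

__all__ = [
    "ChannelMLPWeights",
    "SpatialConvKernel",
    "channel_attention",
    "spatial_attention",
    "ChannelAttention",
    "SpatialAttention",
    "DualAttentionBlock",
]


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")


@dataclass
class ChannelMLPWeights:
    """Shared two-layer MLP of the channel-attention branch.

    ``w0`` has shape (C/r, C) and ``w1`` shape (C, C/r); biases are off by
    default because the gating is written purely as W1·relu(W0·v).
    """

    w0: np.ndarray
    w1: np.ndarray
    r: int
    b0: np.ndarray | None = None
    b1: np.ndarray | None = None

    @classmethod
    def random(cls, rng: np.random.Generator, channels: int, r: int = 16, bias: bool = False) -> "ChannelMLPWeights":
        if channels % r:
            raise ConfigurationError(f"reduction ratio r={r} must divide C={channels}")
        hidden = channels // r
        w0 = he_init(rng, (hidden, channels), channels)
        w1 = he_init(rng, (channels, hidden), hidden)
        b0 = np.zeros(hidden, dtype=np.float32) if bias else None
        b1 = np.zeros(channels, dtype=np.float32) if bias else None
        return cls(w0=w0, w1=w1, r=r, b0=b0, b1=b1)


@dataclass
class SpatialConvKernel:
    """The 7x7 convolution of the spatial-attention branch: one output
    channel over the stacked [mean; max] channel-pooled planes, padding 3."""

    kernel: np.ndarray  # (1, 2, 7, 7)
    bias: float = 0.0
    padding: int = 3

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=np.float32)
        if self.kernel.shape != (1, 2, 7, 7):
            raise ConfigurationError(f"spatial kernel must be (1,2,7,7), got {self.kernel.shape}")

    @classmethod
    def random(cls, rng: np.random.Generator) -> "SpatialConvKernel":
        return cls(kernel=he_init(rng, (1, 2, 7, 7), 2 * 49), bias=0.0)


def _channel_attention_t(f: Tensor, w0: Tensor, w1: Tensor, b0: Tensor | None, b1: Tensor | None) -> Tensor:
    c = f.shape[0]
    flat = G.reshape(f, (c, -1))
    pooled = (G.tmean(flat, axis=1), G.tmax(flat, axis=1))  # avg first, max second
    branches = []
    for v in pooled:
        h = G.matmul(G.reshape(v, (1, c)), G.transpose(w0, (1, 0)))
        if b0 is not None:
            h = G.add(h, b0)
        h = G.relu(h)
        o = G.matmul(h, G.transpose(w1, (1, 0)))
        if b1 is not None:
            o = G.add(o, b1)
        branches.append(o)
    return G.reshape(G.sigmoid(G.add(*branches)), (c, 1, 1))


def _spatial_attention_t(f: Tensor, kernel: Tensor, bias: Tensor | None, padding: int) -> Tensor:
    pooled = G.concat([G.tmean_channel(f), G.tmax_channel(f)], axis=0)  # (2, H, W)
    return G.sigmoid(G.conv2d(pooled, kernel, bias, padding))


def channel_attention(f: np.ndarray, w: ChannelMLPWeights) -> np.ndarray:
    """Channel attention map of a (C,H,W) feature map; returns (C,1,1)."""
    f = np.asarray(f, dtype=np.float32)
    if f.ndim != 3:
        raise ValidationError(f"feature map must be (C,H,W), got {f.shape}")
    _check_finite(f, "feature map")
    c = f.shape[0]
    if c % w.r:
        raise ConfigurationError(f"reduction ratio r={w.r} must divide C={c}")
    if w.w0.shape != (c // w.r, c) or w.w1.shape != (c, c // w.r):
        raise ConfigurationError(
            f"MLP weight shapes {w.w0.shape}/{w.w1.shape} inconsistent with C={c}, r={w.r}"
        )
    out = _channel_attention_t(
        Tensor(f),
        Tensor(w.w0),
        Tensor(w.w1),
        None if w.b0 is None else Tensor(w.b0),
        None if w.b1 is None else Tensor(w.b1),
    )
    return out.data


def spatial_attention(f: np.ndarray, k: SpatialConvKernel) -> np.ndarray:
    """Spatial attention map of a (C,H,W) feature map; returns (1,H,W)."""
    f = np.asarray(f, dtype=np.float32)
    if f.ndim != 3:
        raise ValidationError(f"feature map must be (C,H,W), got {f.shape}")
    _check_finite(f, "feature map")
    out = _spatial_attention_t(
        Tensor(f),
        Tensor(k.kernel),
        Tensor(np.asarray([k.bias], dtype=np.float32)),
        k.padding,
    )
    return out.data


class ChannelAttention(Module):
    def __init__(self, rng: np.random.Generator, channels: int, r: int = 16, bias: bool = False):
        if channels % r:
            raise ConfigurationError(f"reduction ratio r={r} must divide C={channels}")
        hidden = channels // r
        self.w0 = Parameter(he_init(rng, (hidden, channels), channels))
        self.w1 = Parameter(he_init(rng, (channels, hidden), hidden))
        self.b0 = Parameter(np.zeros(hidden)) if bias else None
        self.b1 = Parameter(np.zeros(channels)) if bias else None

    def __call__(self, f: Tensor) -> Tensor:
        return _channel_attention_t(f, self.w0, self.w1, self.b0, self.b1)


class SpatialAttention(Module):
    def __init__(self, rng: np.random.Generator):
        self.kernel = Parameter(he_init(rng, (1, 2, 7, 7), 2 * 49))
        self.bias = Parameter(np.zeros(1))

    def __call__(self, f: Tensor) -> Tensor:
        return _spatial_attention_t(f, self.kernel, self.bias, padding=3)


class DualAttentionBlock(Module):
    """Residual channel-then-spatial gating of the bottleneck feature map."""

    def __init__(self, rng: np.random.Generator, channels: int, r: int = 16):
        self.conv = Conv2d(rng, channels, channels, k=1)
        self.channel = ChannelAttention(rng, channels, r=r)
        self.spatial = SpatialAttention(rng)

    def __call__(self, g: Tensor) -> Tensor:
        f = self.conv(g)
        gated = G.mul(f, self.channel(f))
        out = G.add(f, G.mul(gated, self.spatial(gated)))
        if out.shape != f.shape:
            raise AssertionError(f"dual-attention shape drift: {out.shape} vs {f.shape}")
        return out

    def forward_array(self, g: np.ndarray) -> np.ndarray:
        """Numpy convenience wrapper around :meth:`__call__`."""
        g = np.asarray(g, dtype=np.float32)
        _check_finite(g, "feature map")
        return self(Tensor(g)).data


def dual_attention_block(g: np.ndarray, block: DualAttentionBlock) -> np.ndarray:
    """Apply a dual-attention block to a (C,H,W) encoder output."""
    return block.forward_array(g)
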