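"""Vision-transformer re-encoder used inside a skip connection.

A square feature map is cut into a fixed 4x4 grid of 16 patches, each
flattened (channel-major) and linearly projected to a D-dimensional token;
a learned position embedding is added:

    z_0 = [p^1 X; ...; p^16 X] + X_pos

The token sequence then passes through n pre-norm transformer layers

    z' = MSA(LN(z)) + z
    z  = MLP(LN(z')) + z'

with standard scaled-dot-product multi-head attention (head width D/h) and
a two-layer GELU MLP of hidden width 4D.  A learned inverse projection
X_inv maps each token back to a flattened patch, and the patches are
reassembled into a map of the original shape.  The refined map replaces
(or, optionally, is concatenated to) the raw skip features.
"""

from __future__ import annotations

import numpy as np

from . import grad as G
from .exceptions import ConfigurationError, ValidationError
from .grad import Tensor
from .nn import LayerNorm, Linear, Module, Parameter

__all__ = [
    "GRID",
    "patchify",
    "unpatchify",
    "embed_patches",
    "MultiHeadSelfAttention",
    "EncoderLayer",
    "encoder_layer",
    "TransformerSkip",
    "transformer_skip",
]

GRID = 4  # patches per side; 16 patches total


def _check_patchable(c: int, h: int, w: int) -> int:
    if h != w:
        raise ValidationError(f"patchify needs a square map, got {h}x{w}")
    if h % GRID:
        raise ValidationError(f"map side {h} not divisible by the {GRID}x{GRID} patch grid")
    return h // GRID


def patchify(f: np.ndarray) -> np.ndarray:
    """Cut a (C,H,W) map into 16 flattened patches, row-major over the grid.

    Returns a (16, P*P*C) array with P = H/4; patch vectors are the
    channel-major ravel of each (C,P,P) block, so the operation is lossless.
    """
    f = np.asarray(f)
    c, h, w = f.shape
    p = _check_patchable(c, h, w)
    blocks = f.reshape(c, GRID, p, GRID, p).transpose(1, 3, 0, 2, 4)
    return np.ascontiguousarray(blocks.reshape(GRID * GRID, c * p * p))


def unpatchify(patches: np.ndarray, channels: int, side: int) -> np.ndarray:
    """Inverse of :func:`patchify`: (16, P*P*C) back to (C, side, side)."""
    p = side // GRID
    blocks = np.asarray(patches).reshape(GRID, GRID, channels, p, p)
    return np.ascontiguousarray(blocks.transpose(2, 0, 3, 1, 4).reshape(channels, side, side))


def _patchify_t(f: Tensor) -> Tensor:
    c, h, w = f.shape
    p = _check_patchable(c, h, w)
    x = G.reshape(f, (c, GRID, p, GRID, p))
    x = G.transpose(x, (1, 3, 0, 2, 4))
    return G.reshape(x, (GRID * GRID, c * p * p))


def _unpatchify_t(patches: Tensor, channels: int, side: int) -> Tensor:
    p = side // GRID
    x = G.reshape(patches, (GRID, GRID, channels, p, p))
    x = G.transpose(x, (2, 0, 3, 1, 4))
    return G.reshape(x, (channels, side, side))


def embed_patches(patches: np.ndarray, x_proj: np.ndarray, x_pos: np.ndarray) -> np.ndarray:
    """Linear patch embedding plus position embedding: z0 = [p^i X] + X_pos."""
    patches = np.asarray(patches)
    if patches.shape[0] != GRID * GRID:
        raise ValidationError(f"expected {GRID * GRID} patches, got {patches.shape[0]}")
    if patches.shape[1] != x_proj.shape[0]:
        raise ValidationError(f"patch length {patches.shape[1]} does not match projection rows {x_proj.shape[0]}")
    return patches @ x_proj + x_pos


class MultiHeadSelfAttention(Module):
    def __init__(self, rng: np.random.Generator, dim: int, heads: int):
        if dim % heads:
            raise ConfigurationError(f"head count h={heads} must divide D={dim}")
        self.heads = heads
        self.dk = dim // heads
        self.wq = Linear(rng, dim, dim)
        self.wk = Linear(rng, dim, dim)
        self.wv = Linear(rng, dim, dim)
        self.wo = Linear(rng, dim, dim)

    def _split(self, z: Tensor, tokens: int) -> Tensor:
        return G.transpose(G.reshape(z, (tokens, self.heads, self.dk)), (1, 0, 2))

    def __call__(self, z: Tensor) -> Tensor:
        tokens, dim = z.shape
        q = self._split(self.wq(z), tokens)
        k = self._split(self.wk(z), tokens)
        v = self._split(self.wv(z), tokens)
        scores = G.mul(G.matmul(q, G.transpose(k, (0, 2, 1))), G.as_tensor(np.float32(1.0 / np.sqrt(self.dk))))
        attn = G.softmax(scores, axis=-1)
        heads = G.matmul(attn, v)  # (h, T, dk)
        merged = G.reshape(G.transpose(heads, (1, 0, 2)), (tokens, dim))
        return self.wo(merged)


class FeedForward(Module):
    def __init__(self, rng: np.random.Generator, dim: int, hidden: int):
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def __call__(self, z: Tensor) -> Tensor:
        return self.fc2(G.gelu(self.fc1(z)))


class EncoderLayer(Module):
    """One pre-norm MSA + MLP residual pair."""

    def __init__(self, rng: np.random.Generator, dim: int, heads: int, mlp_ratio: int = 4):
        self.ln1 = LayerNorm(dim)
        self.msa = MultiHeadSelfAttention(rng, dim, heads)
        self.ln2 = LayerNorm(dim)
        self.mlp = FeedForward(rng, dim, mlp_ratio * dim)

    def __call__(self, z: Tensor) -> Tensor:
        z = G.add(self.msa(self.ln1(z)), z)
        return G.add(self.mlp(self.ln2(z)), z)


def encoder_layer(z: np.ndarray, layer: EncoderLayer) -> np.ndarray:
    """Numpy wrapper: run one encoder layer on a (T, D) token matrix."""
    z = np.asarray(z, dtype=np.float32)
    if not np.all(np.isfinite(z)):
        raise ValidationError("token sequence contains non-finite values")
    return layer(Tensor(z)).data


class TransformerSkip(Module):
    """Re-encode a (C, side, side) skip feature map through n ViT layers."""

    def __init__(
        self,
        rng: np.random.Generator,
        channels: int,
        side: int,
        n_layers: int = 2,
        dim: int = 128,
        heads: int = 4,
        mode: str = "replace",
    ):
        if mode not in ("replace", "concat"):
            raise ConfigurationError(f"unknown skip mode {mode!r}")
        p = _check_patchable(channels, side, side)
        self.channels = channels
        self.side = side
        self.mode = mode
        patch_len = channels * p * p
        self.proj = Linear(rng, patch_len, dim, bias=False)
        self.pos = Parameter(rng.normal(0.0, 0.02, size=(GRID * GRID, dim)).astype(np.float32))
        self.layers = [EncoderLayer(rng, dim, heads) for _ in range(n_layers)]
        self.inv = Linear(rng, dim, patch_len)

    def __call__(self, f: Tensor) -> Tensor:
        z = G.add(self.proj(_patchify_t(f)), self.pos)
        for layer in self.layers:
            z = layer(z)
        refined = _unpatchify_t(self.inv(z), self.channels, self.side)
        if self.mode == "concat":
            return G.concat([f, refined], axis=0)
        return refined

    def forward_array(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=np.float32)
        if not np.all(np.isfinite(f)):
            raise ValidationError("feature map contains non-finite values")
        return self(Tensor(f)).data


def transformer_skip(f: np.ndarray, module: TransformerSkip) -> np.ndarray:
    """Apply a transformer skip re-encoder to a (C,H,W) map (numpy in/out)."""
    return module.forward_array(f)
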