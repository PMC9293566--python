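"""TiM-Net assembly: multiscale encoder, attention bottleneck, transformer
skips, deeply supervised decoder, training and prediction.

The network is an M-Net-style U-shaped segmenter with four encoder levels.
A max-pooled image pyramid (scales 1, 1/2, 1/4, 1/8) feeds each encoder
stage alongside the pooled previous stage; the deepest map passes through
the dual-attention block; skip connections at configurable levels are
re-encoded by a small vision transformer; each of the four decoder stages
emits a full-resolution sigmoid side output (Side5 coarsest ... Side8
finest).  Training minimises the weighted sum of per-side binary
cross-entropies

    L = sum_i alpha_i * L_i ,   sum_i alpha_i = 1,

and the deployable prediction is either the Side7 map or the SideOut
convex fusion of all four maps.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import grad as G
from .attention import DualAttentionBlock
from .exceptions import ConfigurationError, ValidationError
from .grad import Tensor
from .nn import Adam, Conv2d, Module
from .transformer import TransformerSkip

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "LossWeights",
    "SideOutputs",
    "TiMNet",
    "multiscale_pyramid",
    "sideout_fuse",
    "weighted_loss",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

#: Tuned side-output fusion weights (Side5..Side8); the equal scheme is
#: (0.25, 0.25, 0.25, 0.25).
TUNED_ALPHA = (0.10, 0.25, 0.25, 0.40)


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    base_channels doubles per level (base, 2b, 4b, 8b).  transformer_levels
    selects which skip connections (2, 3 and/or 4) are re-encoded by the
    transformer.  backbone_kind 'mnet' enables the multiscale input pyramid;
    'unet' is the plain single-input variant.
    """

    base_channels: int = 16
    depth: int = 4
    transformer_levels: tuple[int, ...] = (2,)
    use_dual_attention: bool = True
    backbone_kind: str = "mnet"
    input_size: int = 64
    in_channels: int = 3
    attention_r: int = 16
    transformer_layers: int = 2
    transformer_dim: int = 128
    transformer_heads: int = 4
    seed: int = 0

    def __post_init__(self):
        self.transformer_levels = tuple(sorted(int(l) for l in self.transformer_levels))
        self.validate()

    def validate(self) -> None:
        if self.backbone_kind not in ("mnet", "unet"):
            raise ConfigurationError(f"backbone_kind must be 'mnet' or 'unet', got {self.backbone_kind!r}")
        if self.depth != 4:
            raise ConfigurationError("only depth=4 is supported")
        if not set(self.transformer_levels) <= {2, 3, 4}:
            raise ConfigurationError(f"transformer_levels must be a subset of {{2,3,4}}, got {self.transformer_levels}")
        # deepest map is input_size / 2^(depth-1); it must still split 4x4
        if self.input_size % (2 ** (self.depth - 1) * 4):
            raise ConfigurationError(f"input_size {self.input_size} must be divisible by {2 ** (self.depth - 1) * 4}")
        deepest_c = self.base_channels * 2 ** (self.depth - 1)
        if self.use_dual_attention and deepest_c % self.attention_r:
            raise ConfigurationError(f"attention_r={self.attention_r} must divide bottleneck channels {deepest_c}")
        if self.transformer_dim % self.transformer_heads:
            raise ConfigurationError("transformer_heads must divide transformer_dim")

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**k for k in range(self.depth))


@dataclass
class TrainConfig:
    learning_rate: float = 0.0015
    batch_size: int = 2
    epochs: int = 100
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass
class LossWeights:
    """Convex fusion/loss weights for Side5..Side8 (normalised on load)."""

    alpha: tuple[float, float, float, float] = TUNED_ALPHA

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=np.float64)
        if a.shape != (4,):
            raise ValidationError(f"exactly 4 side weights required, got {a.shape}")
        if (a < 0).any():
            raise ValidationError("side weights must be nonnegative")
        if a.sum() <= 0:
            raise ValidationError("side weights must not all be zero")
        self.alpha = tuple(float(x) for x in a / a.sum())


@dataclass
class SideOutputs:
    """Four full-resolution vessel-probability maps plus their logits."""

    probs: list[np.ndarray]
    logits: list[np.ndarray]

    def __post_init__(self):
        if len(self.probs) != 4 or len(self.logits) != 4:
            raise ValidationError("exactly 4 side outputs expected")

    @property
    def side7(self) -> np.ndarray:
        return self.probs[2]


def multiscale_pyramid(image: np.ndarray, levels: int = 4) -> list[np.ndarray]:
    """Successive 2x2 max-pools of an (...,H,W) raster; scale 0 is the input."""
    image = np.asarray(image)
    h, w = image.shape[-2:]
    if h % 2 ** (levels - 1) or w % 2 ** (levels - 1):
        raise ValidationError(f"image size {h}x{w} not divisible by {2 ** (levels - 1)}")
    out = [image]
    cur = image
    for _ in range(levels - 1):
        hh, ww = cur.shape[-2:]
        cur = cur.reshape(*cur.shape[:-2], hh // 2, 2, ww // 2, 2).max(axis=(-3, -1))
        out.append(cur)
    return out


def sideout_fuse(maps: Sequence[np.ndarray], weights: LossWeights) -> np.ndarray:
    """SideOut: the convex weighted sum of the four side probability maps."""
    maps = [np.asarray(m, dtype=np.float64) for m in maps]
    if len(maps) != 4:
        raise ValidationError(f"expected 4 side maps, got {len(maps)}")
    return sum(a * m for a, m in zip(weights.alpha, maps))


def weighted_loss(s: SideOutputs, gt: np.ndarray, w: LossWeights) -> float:
    """L = sum_i alpha_i * BCE(side_i, gt), pixel-mean per side."""
    gt = np.asarray(gt)
    if not np.isin(gt, (0, 1)).all():
        raise ValidationError("ground truth must be binary {0,1}")
    total = 0.0
    eps = 1e-7
    for a, p in zip(w.alpha, s.probs):
        if p.shape != gt.shape:
            raise ValidationError(f"side map shape {p.shape} != ground truth {gt.shape}")
        pc = np.clip(p.astype(np.float64), eps, 1 - eps)
        total += a * float(-(gt * np.log(pc) + (1 - gt) * np.log(1 - pc)).mean())
    return total


class ConvBlock(Module):
    """Two 3x3 convolutions with rectified-linear activations."""

    def __init__(self, rng, cin: int, cout: int):
        self.c1 = Conv2d(rng, cin, cout, 3)
        self.c2 = Conv2d(rng, cout, cout, 3)

    def __call__(self, x: Tensor) -> Tensor:
        return G.relu(self.c2(G.relu(self.c1(x))))


class TiMNet(Module):
    """The full segmentation network (see module docstring)."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        cs = config.channels  # (b, 2b, 4b, 8b)
        cin = config.in_channels

        self.enc = [ConvBlock(rng, cin, cs[0])]
        self.img_convs = []
        for k in range(1, 4):
            enc_in = cs[k - 1]
            if config.backbone_kind == "mnet":
                self.img_convs.append(Conv2d(rng, cin, cs[k - 1], 3))
                enc_in += cs[k - 1]
            self.enc.append(ConvBlock(rng, enc_in, cs[k]))

        self.attn = DualAttentionBlock(rng, cs[3], r=config.attention_r) if config.use_dual_attention else None

        self.skips: dict[int, TransformerSkip] = {}
        for level in config.transformer_levels:
            side = config.input_size // 2 ** (level - 1)
            self.skips[level] = TransformerSkip(
                rng,
                cs[level - 1],
                side,
                n_layers=config.transformer_layers,
                dim=config.transformer_dim,
                heads=config.transformer_heads,
            )
        # parameter discovery walks lists, not dicts
        self._skip_modules = [self.skips[l] for l in sorted(self.skips)]

        self.dec4 = ConvBlock(rng, cs[3], cs[3])
        self.dec3 = ConvBlock(rng, cs[3] + cs[2], cs[2])
        self.dec2 = ConvBlock(rng, cs[2] + cs[1], cs[1])
        self.dec1 = ConvBlock(rng, cs[1] + cs[0], cs[0])
        self.side_heads = [Conv2d(rng, c, 1, 1) for c in (cs[3], cs[2], cs[1], cs[0])]

    def forward_tensors(self, image: np.ndarray) -> list[Tensor]:
        """Run the network; returns the four full-resolution side logits
        (Side5..Side8) as graph tensors."""
        cfg = self.config
        image = np.asarray(image, dtype=np.float32)
        if image.ndim == 2:
            image = image[None]
        if image.shape != (cfg.in_channels, cfg.input_size, cfg.input_size):
            raise ValidationError(
                f"expected image of shape ({cfg.in_channels},{cfg.input_size},{cfg.input_size}), got {image.shape}"
            )
        pyramid = multiscale_pyramid(image) if cfg.backbone_kind == "mnet" else [image]

        feats = [self.enc[0](Tensor(pyramid[0]))]
        for k in range(1, 4):
            pooled = G.maxpool2d(feats[k - 1])
            if cfg.backbone_kind == "mnet":
                img_feat = G.relu(self.img_convs[k - 1](Tensor(pyramid[k])))
                stage_in = G.concat([pooled, img_feat], axis=0)
            else:
                stage_in = pooled
            feats.append(self.enc[k](stage_in))

        skips = feats[:3]
        deepest = feats[3]
        for level, module in self.skips.items():
            if level == 4:
                deepest = module(deepest)
            else:
                skips[level - 1] = module(skips[level - 1])

        bottleneck = self.attn(deepest) if self.attn is not None else deepest

        d4 = self.dec4(bottleneck)
        d3 = self.dec3(G.concat([_up2(d4), skips[2]], axis=0))
        d2 = self.dec2(G.concat([_up2(d3), skips[1]], axis=0))
        d1 = self.dec1(G.concat([_up2(d2), skips[0]], axis=0))

        size = cfg.input_size
        logits = []
        for head, feat in zip(self.side_heads, (d4, d3, d2, d1)):
            logit = head(feat)
            if logit.shape[-1] != size:
                logit = G.interp_bilinear(logit, size, size)
            logits.append(G.reshape(logit, (size, size)))
        return logits

    def forward(self, image: np.ndarray) -> SideOutputs:
        logits = self.forward_tensors(image)
        arr = [l.data.copy() for l in logits]
        probs = [G._expit(a.astype(np.float64)) for a in arr]
        return SideOutputs(probs=probs, logits=arr)


def _up2(x: Tensor) -> Tensor:
    _, h, w = x.shape
    return G.interp_bilinear(x, 2 * h, 2 * w)


def forward(image: np.ndarray, config: NetworkConfig) -> SideOutputs:
    """Build a freshly initialised network from ``config`` and run it."""
    return TiMNet(config).forward(image)


@dataclass
class TrainResult:
    model: TiMNet
    history: list[dict] = field(default_factory=list)


def train(
    dataset: Sequence,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    loss_weights: LossWeights | None = None,
    log_cb: Callable[[dict], None] | None = None,
) -> TrainResult:
    """Optimise the weighted deep-supervision loss with Adam.

    ``dataset`` yields objects with ``image`` (C,H,W in [0,1]) and ``mask``
    (H,W binary) attributes, or (image, mask) tuples.  Fully deterministic
    for a fixed seed on one device.
    """
    items = [_as_pair(it) for it in dataset]
    if not items:
        raise ValidationError("empty training dataset")
    weights = loss_weights or LossWeights()
    model = TiMNet(net_cfg)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    order_rng = np.random.default_rng(train_cfg.seed)
    history: list[dict] = []
    for epoch in range(train_cfg.epochs):
        perm = order_rng.permutation(len(items))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(items), train_cfg.batch_size):
            batch = [items[i] for i in perm[start : start + train_cfg.batch_size]]
            opt.zero_grad()
            batch_loss = 0.0
            for image, mask in batch:
                logits = model.forward_tensors(image)
                terms = [
                    G.mul(G.bce_with_logits(l, mask), G.as_tensor(np.float32(a)))
                    for l, a in zip(logits, weights.alpha)
                ]
                loss = terms[0]
                for t in terms[1:]:
                    loss = G.add(loss, t)
                loss.backward(np.asarray(1.0 / len(batch), dtype=np.float32))
                batch_loss += float(loss.data) / len(batch)
            if not np.isfinite(batch_loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {batch_loss}; aborting")
            opt.step()
            epoch_loss += batch_loss
            n_batches += 1
        entry = {"epoch": epoch, "loss": epoch_loss / n_batches}
        history.append(entry)
        if log_cb is not None:
            log_cb(entry)
    return TrainResult(model=model, history=history)


def _as_pair(item) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(item, "image") and hasattr(item, "mask"):
        return np.asarray(item.image, dtype=np.float32), np.asarray(item.mask)
    image, mask = item[0], item[1]
    return np.asarray(image, dtype=np.float32), np.asarray(mask)


def predict(
    image: np.ndarray,
    model: TiMNet,
    variant: str = "sideout",
    threshold: float = 0.5,
    loss_weights: LossWeights | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability map and thresholded mask for one image.

    variant 'side7' uses the Side7 map alone; 'sideout' the weighted fusion.
    """
    if variant not in ("side7", "sideout"):
        raise ConfigurationError(f"variant must be 'side7' or 'sideout', got {variant!r}")
    s = model.forward(image)
    prob = s.side7 if variant == "side7" else sideout_fuse(s.probs, loss_weights or LossWeights())
    return prob, (prob >= threshold).astype(np.uint8)


def save_checkpoint(path, model: TiMNet) -> None:
    """Single-file checkpoint: every parameter array plus the config."""
    cfg = json.dumps(asdict(model.config))
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **model.state())


def load_checkpoint(path) -> TiMNet:
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        cfg_dict["transformer_levels"] = tuple(cfg_dict["transformer_levels"])
        model = TiMNet(NetworkConfig(**cfg_dict))
        model.load_state({k: data[k] for k in data.files if k != "__config__"})
    return model
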