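"""The ResNet-Transformer cascade for 12-class MI localization.

A five-stage ResNet-50 backbone (7x7 stem, max-pool, bottleneck stacks
repeated 3/4/6/3 — 50 trainable weight layers counting the stem, the 48
bottleneck convolutions and the classification head) turns a 3 x 224 x 224
time–frequency image into a 7 x 7 x 2048 feature map.  A 1 x 1 convolution
compresses channels to d = 512, the map is flattened row-major into 49 tokens,
learnable per-position embeddings are added, a learnable class token is
prepended, and a 3-layer / 8-head Transformer encoder models global context.
The class-token state feeds a fully connected layer whose softmax yields the
12 class probabilities.

``width_divisor`` and ``input_side`` scale every stage jointly so the same
architecture runs at desk scale; ablation variants (backbone-only with a
global-pool head, and a patchify ViT that skips the backbone) share the
config surface.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.functional import softmax

#: Bottleneck stage plan: (mid_channels, n_blocks, stride) at full width.
STAGE_PLAN = ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2))


@dataclass
class RtcnConfig:
    n_classes: int = 12
    input_side: int = 224
    width_divisor: int = 1          # divides every channel width
    compressed_dim: int = 512       # d after the 1x1 compression
    n_heads: int = 8
    n_encoder_layers: int = 3
    ff_dim: int | None = None       # defaults to 4 * compressed_dim
    dropout: float = 0.1
    variant: str = "rtcn"           # "rtcn" | "resnet" | "vit"
    vit_patch: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.compressed_dim % self.n_heads:
            raise ValueError("compressed_dim must be divisible by n_heads")
        if self.input_side % 32:
            raise ValueError("input side must be divisible by 32 (stride plan)")
        if self.variant not in ("rtcn", "resnet", "vit"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def grid_side(self) -> int:
        if self.variant == "vit":
            return self.input_side // self.vit_patch
        return self.input_side // 32

    @property
    def n_tokens(self) -> int:
        return self.grid_side ** 2

    @property
    def feedforward_dim(self) -> int:
        return self.ff_dim if self.ff_dim is not None else 4 * self.compressed_dim


class Bottleneck(nn.Module):
    """1x1 -> 3x3 -> 1x1 residual unit; stride (when used) sits on the first
    1x1 convolution and on the projection shortcut."""

    def __init__(self, c_in, c_mid, c_out, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_mid, 1, rng, stride=stride)
        self.bn1 = nn.BatchNorm2d(c_mid)
        self.conv2 = nn.Conv2d(c_mid, c_mid, 3, rng, pad=1)
        self.bn2 = nn.BatchNorm2d(c_mid)
        self.conv3 = nn.Conv2d(c_mid, c_out, 1, rng)
        self.bn3 = nn.BatchNorm2d(c_out)
        self.relu1, self.relu2, self.relu_out = nn.ReLU(), nn.ReLU(), nn.ReLU()
        if stride != 1 or c_in != c_out:
            self.proj = nn.Conv2d(c_in, c_out, 1, rng, stride=stride)
            self.proj_bn = nn.BatchNorm2d(c_out)
        else:
            self.proj = None

    def forward(self, x):
        main = self.relu2(self.bn2(self.conv2(
            self.relu1(self.bn1(self.conv1(x))))))
        main = self.bn3(self.conv3(main))
        skip = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return self.relu_out(main + skip)

    def backward(self, g):
        g = self.relu_out.backward(g)
        gm = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(self.relu2.backward(
                self.conv3.backward(self.bn3.backward(g))))))))
        if self.proj is not None:
            gs = self.proj.backward(self.proj_bn.backward(g))
        else:
            gs = g
        return gm + gs


def build_backbone(config: RtcnConfig, rng) -> nn.Sequential:
    """Five-stage ResNet-50 (width optionally divided) as one Sequential.

    For a 3 x 224 x 224 input the final stage emits ``2048/width_divisor``
    channels on a 7 x 7 grid.
    """
    div = config.width_divisor
    stem_c = max(1, 64 // div)
    layers = [
        nn.Conv2d(3, stem_c, 7, rng, stride=2, pad=3),
        nn.BatchNorm2d(stem_c),
        nn.ReLU(),
        nn.MaxPool2d(3, 2, 1),
    ]
    c_in = stem_c
    for mid_full, blocks, stride in STAGE_PLAN:
        mid = max(1, mid_full // div)
        out = mid * 4
        stage = []
        for b in range(blocks):
            stage.append(Bottleneck(c_in, mid, out, stride if b == 0 else 1, rng))
            c_in = out
        layers.append(nn.Sequential(*stage))
    return nn.Sequential(*layers)


def backbone_out_channels(config: RtcnConfig) -> int:
    return max(1, STAGE_PLAN[-1][0] // config.width_divisor) * 4


def count_weight_layers(config: RtcnConfig) -> int:
    """Trainable weight layers per the standard ResNet counting convention:
    stem conv + three convs per bottleneck + the final fully connected head
    (projection shortcuts are not counted)."""
    return 1 + 3 * sum(blocks for _, blocks, _ in STAGE_PLAN) + 1


class TokenCompressor(nn.Module):
    """1x1 channel compression, row-major flatten to tokens, learnable
    positional embedding, class-token prepend, dropout."""

    def __init__(self, c_in, config: RtcnConfig, rng):
        super().__init__()
        d, t = config.compressed_dim, config.n_tokens
        self.compress = nn.Conv2d(c_in, d, 1, rng, bias=True)
        self.pos_embed = nn.Parameter(rng.normal(0.0, 0.02, size=(t, d)))
        self.cls_token = nn.Parameter(rng.normal(0.0, 0.02, size=(d,)))
        self.drop = nn.Dropout(config.dropout, rng)
        self.grid = config.grid_side

    def forward(self, feat):
        z = self.compress(feat)                       # (N, d, H, W)
        n, d, h, w = z.shape
        if (h, w) != (self.grid, self.grid):
            raise ValueError(f"feature grid {h}x{w} does not match config "
                             f"{self.grid}x{self.grid}")
        tokens = z.reshape(n, d, h * w).transpose(0, 2, 1)   # row-major flatten
        tokens = tokens + self.pos_embed.value
        cls = np.broadcast_to(self.cls_token.value, (n, 1, d))
        return self.drop(np.concatenate([cls, tokens], axis=1))

    def backward(self, g):
        g = self.drop.backward(g)
        self.cls_token.grad += g[:, 0, :].sum(axis=0)
        gt = g[:, 1:, :]
        self.pos_embed.grad += gt.sum(axis=0)
        n, t, d = gt.shape
        gz = gt.transpose(0, 2, 1).reshape(n, d, self.grid, self.grid)
        return self.compress.backward(gz)


class PatchEmbed(nn.Module):
    """Linear patchify for the standalone ViT ablation."""

    def __init__(self, config: RtcnConfig, rng):
        super().__init__()
        p = config.vit_patch
        self.p = p
        self.proj = nn.Linear(3 * p * p, config.compressed_dim, rng)
        self.pos_embed = nn.Parameter(
            rng.normal(0.0, 0.02, size=(config.n_tokens, config.compressed_dim)))
        self.cls_token = nn.Parameter(
            rng.normal(0.0, 0.02, size=(config.compressed_dim,)))
        self.drop = nn.Dropout(config.dropout, rng)

    def _patchify(self, x):
        n, c, h, w = x.shape
        p = self.p
        gh, gw = h // p, w // p
        x = x.reshape(n, c, gh, p, gw, p).transpose(0, 2, 4, 1, 3, 5)
        return x.reshape(n, gh * gw, c * p * p)

    def forward(self, x):
        self._x_shape = x.shape
        tokens = self.proj(self._patchify(x)) + self.pos_embed.value
        n, _, d = tokens.shape
        cls = np.broadcast_to(self.cls_token.value, (n, 1, d))
        return self.drop(np.concatenate([cls, tokens], axis=1))

    def backward(self, g):
        g = self.drop.backward(g)
        self.cls_token.grad += g[:, 0, :].sum(axis=0)
        gt = g[:, 1:, :]
        self.pos_embed.grad += gt.sum(axis=0)
        gp = self.proj.backward(gt)
        n, c, h, w = self._x_shape
        p = self.p
        gh, gw = h // p, w // p
        gp = gp.reshape(n, gh, gw, c, p, p).transpose(0, 3, 1, 4, 2, 5)
        return gp.reshape(n, c, h, w)


class RTCN(nn.Module):
    """The full cascade (or an ablation variant, per ``config.variant``).

    ``forward`` returns logits (training needs them); :meth:`predict_proba`
    and :meth:`classify` expose the softmax contract.  After a backward pass
    the activations/gradients of the registered layers (``conv5``, ``tokens``)
    are available for Grad-CAM.
    """

    def __init__(self, config: RtcnConfig | None = None):
        super().__init__()
        self.config = config or RtcnConfig()
        rng = np.random.default_rng(self.config.seed)
        cfg = self.config
        d = cfg.compressed_dim
        if cfg.variant in ("rtcn", "resnet"):
            self.backbone = build_backbone(cfg, rng)
            c_out = backbone_out_channels(cfg)
        if cfg.variant == "rtcn":
            self.tokenizer = TokenCompressor(c_out, cfg, rng)
        elif cfg.variant == "vit":
            self.tokenizer = PatchEmbed(cfg, rng)
        if cfg.variant in ("rtcn", "vit"):
            self.encoder = nn.Sequential(*[
                nn.TransformerEncoderLayer(d, cfg.n_heads, cfg.feedforward_dim,
                                           cfg.dropout, rng)
                for _ in range(cfg.n_encoder_layers)])
            self.head = nn.Linear(d, cfg.n_classes, rng)
        else:  # resnet-only: global average pool + fc
            self.pool = nn.GlobalAvgPool2d()
            self.head = nn.Linear(c_out, cfg.n_classes, rng)

    # -- registered layers for explainability -------------------------------
    def registered_layers(self) -> dict:
        layers = {}
        if hasattr(self, "backbone"):
            layers["conv5"] = self.backbone[-1]
        if hasattr(self, "encoder"):
            layers["tokens"] = self.encoder[-1]
        return layers

    def forward(self, x):
        if x.ndim == 3:
            x = x[None]
        cfg = self.config
        if x.shape[1:] != (3, cfg.input_side, cfg.input_side):
            raise ValueError(
                f"expected input 3x{cfg.input_side}x{cfg.input_side}, got {x.shape[1:]}")
        if cfg.variant == "resnet":
            return self.head(self.pool(self.backbone(x)))
        if cfg.variant == "vit":
            enc = self.encoder(self.tokenizer(x))
        else:
            enc = self.encoder(self.tokenizer(self.backbone(x)))
        self._encoded = enc
        return self.head(enc[:, 0, :])

    def backward(self, g_logits):
        cfg = self.config
        if cfg.variant == "resnet":
            return self.backbone.backward(self.pool.backward(
                self.head.backward(g_logits)))
        g_enc = np.zeros_like(self._encoded)
        g_enc[:, 0, :] = self.head.backward(g_logits)
        g = self.tokenizer.backward(self.encoder.backward(g_enc))
        if cfg.variant == "rtcn":
            g = self.backbone.backward(g)
        return g

    def classify(self, encoded) -> np.ndarray:
        """Softmax class probabilities from an encoded token sequence."""
        return softmax(self.head(encoded[:, 0, :]))

    def predict_proba(self, x) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            p = softmax(self.forward(np.asarray(x, dtype=float)))
        finally:
            self.train(was_training)
        return p

    def predict(self, x) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=-1)
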