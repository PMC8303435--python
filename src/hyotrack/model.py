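"""BiFPN-U-Net(T): the multi-scale segmentation network.

A VGG16-style convolutional encoder produces a five-level feature pyramid
P1..P5 (strides 1..16).  One or more bidirectional feature-pyramid (BiFPN)
layers refine the pyramid with fast-normalized weighted fusion — a top-down
pass (P5 -> P1, nearest upsampling) followed by a bottom-up pass (P1 -> P5,
max-pool downsampling), every node mixing its inputs with learned non-negative
weights.  A bottleneck-transformer block with global multi-head self-attention
runs on the refined P5 only, where the quadratic attention cost is small, so
the network can use global context (e.g. to find a hyoid partly hidden behind
the mandible).  A U-Net-style decoder walks back up the refined pyramid with
skip concatenations from the encoder stages and ends in a 1x1 convolution
producing per-pixel scores for the four classes (background, hyoid bone,
cervical spine, coin).

Weights are always randomly initialized; no transfer learning is used because
the fluoroscopic frames are single-channel and at a roughly fixed object
scale, unlike natural-image pretraining corpora.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor

# convolutions per VGG16 stage
_VGG_STAGE_CONVS = (2, 2, 3, 3, 3)


class ConfigurationError(ValueError):
    pass


@dataclass
class NetworkConfig:
    """Architecture and training hyper-parameters.

    The learning rate is never stored: it follows the linear-scaling rule
    lr = 0.1 * batch_size / 256 (see :meth:`base_lr`).
    """

    input_size: Tuple[int, int] = (224, 224)
    input_channels: int = 1
    num_classes: int = 4
    encoder_widths: Tuple[int, ...] = (64, 128, 256, 512, 512)
    bifpn_channels: int = 64
    bifpn_repeats: int = 1
    bot_heads: int = 4
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    batch_size: int = 8
    max_epochs: int = 500
    patience: int = 20
    seed: int = 0

    @property
    def base_lr(self) -> float:
        return 0.1 * self.batch_size / 256.0

    def validate(self) -> "NetworkConfig":
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ConfigurationError(
                f"input_size {h}x{w} must be divisible by 16 (four 2x downsamplings P1->P5)")
        if len(self.encoder_widths) != 5:
            raise ConfigurationError("encoder_widths must list five pyramid levels P1..P5")
        if self.bifpn_channels <= 0:
            raise ConfigurationError("bifpn_channels must be positive")
        if self.bifpn_repeats < 1:
            raise ConfigurationError("bifpn_repeats must be >= 1")
        if not (0 < self.focal_alpha <= 1):
            raise ConfigurationError("focal_alpha must be in (0, 1]")
        if self.focal_gamma < 0:
            raise ConfigurationError("focal_gamma must be >= 0")
        if self.patience >= self.max_epochs:
            raise ConfigurationError("patience must be smaller than max_epochs")
        if (h // 16) * (w // 16) > 4096:
            raise ConfigurationError(
                "P5 has more than 4096 positions; global attention would be "
                "intractable — use a smaller input or a deeper pyramid")
        return self

    @classmethod
    def desk_scale(cls, **overrides) -> "NetworkConfig":
        """Reduced profile (96x96 input, widths / 4) for CPU-scale runs."""
        defaults = dict(
            input_size=(96, 96),
            encoder_widths=(16, 32, 64, 128, 128),
            bifpn_channels=16,
        )
        defaults.update(overrides)
        return cls(**defaults)


class _EncoderStage(nn.Module):
    def __init__(self, cin, cout, n_convs, rng):
        self.convs = [nn.ConvReLU(cin if i == 0 else cout, cout, 3, rng)
                      for i in range(n_convs)]

    def forward(self, x):
        for c in self.convs:
            x = c(x)
        return x


class BiFPNLayer(nn.Module):
    """One bidirectional pass over a five-level pyramid."""

    def __init__(self, in_channels: List[int], channels: int, rng):
        self.laterals = [nn.Conv2d(c, channels, 1, rng) if c != channels else None
                         for c in in_channels]
        # top-down nodes for levels 3..0 (P4..P1)
        self.td_fuse = [nn.WeightedFusion(2) for _ in range(4)]
        self.td_conv = [nn.ConvReLU(channels, channels, 3, rng) for _ in range(4)]
        # bottom-up nodes for levels 1..4 (P2..P5); P5 node has two inputs
        self.bu_fuse = [nn.WeightedFusion(3) for _ in range(3)] + [nn.WeightedFusion(2)]
        self.bu_conv = [nn.ConvReLU(channels, channels, 3, rng) for _ in range(4)]

    def forward(self, pyramid: List[Tensor]) -> List[Tensor]:
        lat = [p if l is None else l(p) for l, p in zip(self.laterals, pyramid)]
        td = [None] * 5
        td[4] = lat[4]
        for i in (3, 2, 1, 0):
            fused = self.td_fuse[i]([lat[i], T.upsample_nearest2x(td[i + 1])])
            td[i] = self.td_conv[i](fused)
        out = [None] * 5
        out[0] = td[0]
        for i in (1, 2, 3):
            fused = self.bu_fuse[i - 1]([lat[i], td[i], T.maxpool2x2(out[i - 1])])
            out[i] = self.bu_conv[i - 1](fused)
        fused = self.bu_fuse[3]([lat[4], T.maxpool2x2(out[3])])
        out[4] = self.bu_conv[3](fused)
        return out


class BiFPNUNet(nn.Module):
    """See module docstring.  Input (N, 1, H, W) -> logits (N, K, H, W)."""

    def __init__(self, config: NetworkConfig, rng: Optional[np.random.Generator] = None):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed) if rng is None else rng
        widths = list(config.encoder_widths)
        f = config.bifpn_channels
        h, w = config.input_size

        self.stages = []
        cin = config.input_channels
        for cout, n in zip(widths, _VGG_STAGE_CONVS):
            self.stages.append(_EncoderStage(cin, cout, n, rng))
            cin = cout

        self.bifpn = [BiFPNLayer(widths if r == 0 else [f] * 5, f, rng)
                      for r in range(config.bifpn_repeats)]
        self.bot = nn.BotBlock(f, config.bot_heads, h // 16, w // 16, rng)

        # decoder level i consumes up(previous) ++ bifpn[i] ++ encoder skip[i]
        self.dec_conv1 = [nn.ConvReLU(f + f + widths[i], f, 3, rng) for i in range(4)]
        self.dec_conv2 = [nn.ConvReLU(f, f, 3, rng) for i in range(4)]
        self.head = nn.Conv2d(f, config.num_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for i, stage in enumerate(self.stages):
            if i > 0:
                x = T.maxpool2x2(x)
            x = stage(x)
            skips.append(x)
        pyr = skips
        for layer in self.bifpn:
            pyr = layer(pyr)
        d = self.bot(pyr[4])
        for i in (3, 2, 1, 0):
            d = T.concat([T.upsample_nearest2x(d), pyr[i], skips[i]], axis=1)
            d = self.dec_conv2[i](self.dec_conv1[i](d))
        return self.head(d)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def summary(self) -> str:
        lines = [f"BiFPN-U-Net(T)  input {self.config.input_size}, "
                 f"{self.config.num_classes} classes",
                 f"encoder widths {tuple(self.config.encoder_widths)}, "
                 f"bifpn {self.config.bifpn_channels}ch x{self.config.bifpn_repeats}, "
                 f"bot heads {self.config.bot_heads}",
                 f"parameters: {self.num_parameters():,}"]
        return "\n".join(lines)


def build_network(config: NetworkConfig) -> BiFPNUNet:
    """Build a randomly initialized BiFPN-U-Net(T) from ``config`` (seeded)."""
    return BiFPNUNet(config)
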