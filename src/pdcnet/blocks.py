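"""Architectural building blocks: PDCM, channel attention, residuals.

The parallel dilated convolutional module (PDCM) runs five branches over
one input feature map F_in:

    branch 1   1x1 conv (+BN+ReLU)         -> F1   (also maps F_in to the
                                                    module width; call it F_in')
    branch 2   3x3 conv, dilation 2        -> F2   input F1 + F_in'
    branch 3   3x3 conv, dilation 4        -> F3   input F2 + F_in'
    branch 4   3x3 conv, dilation 6        -> F4   input F3 + F_in'
    branch 5   channel attention           -> F5   input F4 + F_in'

    F_out = F1 + F2 + F3 + F4 + F5

With ``use_previous_branch=False`` every branch reads F_in' alone, i.e.
an ordinary parallel multi-dilation pyramid.  "+" is elementwise
addition throughout: branch 1 brings F_in to the common channel width so
all additions are well-typed.

Small dilation rates (2, 4, 6) are used because the lesions of interest
occupy a tiny fraction of the image; very large rates fragment the
receptive field over such small targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (
    BatchNorm2d,
    Conv2d,
    Module,
    Tensor,
    global_avg_pool,
    relu,
    sigmoid,
)

__all__ = [
    "BlockConfig",
    "ConvBNReLU",
    "BasicConvBlock",
    "ChannelAttention",
    "PDCM",
    "Residual",
    "dropblock",
]


@dataclass
class BlockConfig:
    """Hyperparameters shared by the blocks of one network level."""

    in_channels: int
    out_channels: int
    dilation_rates: tuple = (2, 4, 6)
    kernel_size: int = 3
    use_previous_branch: bool = True
    use_cam: bool = True
    cam_reduction: int = 8
    dropblock_rate: float = 0.1
    dropblock_size: int = 5

    def __post_init__(self):
        rates = tuple(self.dilation_rates)
        if any(r <= 0 for r in rates) or list(rates) != sorted(set(rates)):
            raise ValueError(f"dilation rates must be positive and strictly increasing, got {rates}")
        self.dilation_rates = rates
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")


def dropblock(x: Tensor, rate: float, block_size: int, rng: np.random.Generator,
              training: bool) -> Tensor:
    """Structured dropout: zero contiguous block_size^2 regions.

    Seed positions are drawn so the expected fraction of dropped
    activations is ``rate``; the surviving activations are rescaled to
    preserve the expected sum.  Identity in evaluation mode or when
    rate <= 0.  The block size is clamped to the feature-map extent.
    """
    if not training or rate <= 0.0:
        return x
    n, c, h, w = x.data.shape
    b = min(block_size, h, w)
    hs, ws = h - b + 1, w - b + 1
    gamma = (rate / (b * b)) * (h * w) / (hs * ws)
    seeds = rng.random((n, c, hs, ws)) < gamma
    mask = np.zeros((n, c, h, w), dtype=bool)
    for di in range(b):
        for dj in range(b):
            mask[:, :, di:hs + di, dj:ws + dj] |= seeds
    keep = (~mask).astype(x.data.dtype)
    kept = keep.sum()
    if kept == 0:  # pathological draw: drop everything -> keep all instead
        return x
    scale = keep.size / kept
    return x * Tensor(keep * scale)


class ConvBNReLU(Module):
    """conv -> batch norm -> ReLU, the unit every branch is made of."""

    def __init__(self, in_channels, out_channels, kernel_size, rng, dilation=1):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng, dilation=dilation)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x):
        return relu(self.bn(self.conv(x)))


class BasicConvBlock(Module):
    """The 'basic convolution operation' of each level: 3x3 conv + BN +
    ReLU followed by DropBlock regularization (training mode only)."""

    def __init__(self, in_channels, out_channels, rng, kernel_size=3,
                 dropblock_rate=0.1, dropblock_size=5, dropblock_seed=0):
        super().__init__()
        self.unit = ConvBNReLU(in_channels, out_channels, kernel_size, rng)
        self.dropblock_rate = dropblock_rate
        self.dropblock_size = dropblock_size
        self._drop_rng = np.random.default_rng(dropblock_seed)

    def forward(self, x):
        y = self.unit(x)
        return dropblock(y, self.dropblock_rate, self.dropblock_size,
                         self._drop_rng, self.training)


class ChannelAttention(Module):
    """Squeeze-and-excitation style channel gate.

    Global average pooling summarizes each channel, a channel-reducing
    1x1 convolution (ratio ``reduction``) and ReLU form the bottleneck,
    a channel-restoring 1x1 convolution and sigmoid produce per-channel
    weights in (0,1) that rescale the input.
    """

    def __init__(self, channels, rng, reduction=8):
        super().__init__()
        if channels < 1:
            raise ValueError("channels must be >= 1")
        hidden = max(channels // reduction, 1)
        self.squeeze = Conv2d(channels, hidden, 1, rng)
        self.excite = Conv2d(hidden, channels, 1, rng)

    def forward(self, x):
        w = global_avg_pool(x)
        w = relu(self.squeeze(w))
        w = sigmoid(self.excite(w))
        return x * w  # broadcast over H, W


class PDCM(Module):
    """Parallel dilated convolutional module with progressive branch fusion."""

    def __init__(self, cfg: BlockConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.reduce = ConvBNReLU(cfg.in_channels, cfg.out_channels, 1, rng)
        self.dilated = [
            ConvBNReLU(cfg.out_channels, cfg.out_channels, cfg.kernel_size, rng,
                       dilation=d)
            for d in cfg.dilation_rates
        ]
        self.cam = (ChannelAttention(cfg.out_channels, rng, cfg.cam_reduction)
                    if cfg.use_cam else None)

    def forward(self, x, return_branches=False):
        if x.data.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"PDCM expects {self.cfg.in_channels} input channels, got {x.data.shape[1]}")
        f_in = self.reduce(x)  # F1 == F_in'
        branches = [f_in]
        prev = f_in
        for conv in self.dilated:
            inp = prev + f_in if self.cfg.use_previous_branch else f_in
            prev = conv(inp)
            branches.append(prev)
        if self.cam is not None:
            inp = prev + f_in if self.cfg.use_previous_branch else f_in
            branches.append(self.cam(inp))
        out = branches[0]
        for bk in branches[1:]:
            out = out + bk
        if return_branches:
            return out, branches
        return out


class Residual(Module):
    """Additive identity shortcut around a main path.

    When input and output channel counts differ the shortcut passes
    through a bias-free 1x1 projection convolution (no BN) before the
    addition.  The main path must preserve spatial size.
    """

    def __init__(self, main: Module, in_channels: int, out_channels: int, rng):
        super().__init__()
        self.main = main
        self.proj = (Conv2d(in_channels, out_channels, 1, rng, bias=False)
                     if in_channels != out_channels else None)

    def forward(self, x):
        fx = self.main(x)
        shortcut = self.proj(x) if self.proj is not None else x
        if fx.data.shape[2:] != shortcut.data.shape[2:]:
            raise ValueError(
                f"residual spatial mismatch: main {fx.data.shape} vs shortcut {shortcut.data.shape}")
        return fx + shortcut
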