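"""The full encoder-decoder segmentation network and its ablation variants.

A U-Net style architecture: ``depth`` encoder levels, each consisting of
a basic 3x3 convolution block followed by a second feature stage —
either a PDCM (the full model) or a second plain convolution block (the
``no_pdcm`` ablation) — optionally wrapped by an additive residual
shortcut.  2x2 max-pooling halves the spatial size between levels while
the channel count doubles.  The decoder mirrors this with 2x2
transposed convolutions, concatenation of same-resolution encoder
features, and the same two-stage blocks.  A final 1x1 convolution and
sigmoid produce a per-pixel lesion probability map the same size as the
input.

Variants (the ablation lattice):
    no_pdcm           second stage is a plain conv block
    pdcm_no_previous  PDCM with independent parallel branches
    pdcm_previous     PDCM with progressive previous-branch fusion
crossed with ``use_residual`` on/off.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import (
    Conv2d,
    ConvTranspose2d,
    Module,
    Sequential,
    Tensor,
    concat_channels,
    max_pool2x2,
    sigmoid,
)
from .blocks import BasicConvBlock, BlockConfig, PDCM, Residual

__all__ = [
    "VARIANTS",
    "ModelConfig",
    "PDCNet",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
    "receptive_field_report",
    "expected_projection_params",
]

VARIANTS = ("no_pdcm", "pdcm_no_previous", "pdcm_previous")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    depth: number of encoder levels (the paper-scale model uses 5).
    base_channels: width of the first level; doubles per level.  16 by
    default, which keeps desk-scale training fast while preserving the
    doubling pattern.  Input H and W must be divisible by 2**(depth-1).
    """

    depth: int = 5
    base_channels: int = 16
    input_channels: int = 1
    variant: str = "pdcm_previous"
    use_residual: bool = True
    dilation_rates: tuple = (2, 4, 6)
    kernel_size: int = 3
    cam_reduction: int = 8
    dropblock_rate: float = 0.1
    dropblock_size: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        self.dilation_rates = tuple(self.dilation_rates)

    @property
    def channels(self):
        return [self.base_channels * 2 ** i for i in range(self.depth)]

    def validate_input_size(self, h, w):
        m = 2 ** (self.depth - 1)
        if h % m or w % m:
            raise ValueError(
                f"input size {h}x{w} is not divisible by 2^(depth-1)={m}; "
                f"pad the image (e.g. pdcnet.io.pad_to_multiple) or reduce depth")


class _LevelBlock(Module):
    """conv block + second stage (PDCM or second conv block), optionally
    residual-wrapped around the pair."""

    def __init__(self, cfg: ModelConfig, in_ch, out_ch, rng, drop_seed):
        super().__init__()
        basic = BasicConvBlock(
            in_ch, out_ch, rng, kernel_size=cfg.kernel_size,
            dropblock_rate=cfg.dropblock_rate, dropblock_size=cfg.dropblock_size,
            dropblock_seed=drop_seed)
        if cfg.variant == "no_pdcm":
            second = BasicConvBlock(
                out_ch, out_ch, rng, kernel_size=cfg.kernel_size,
                dropblock_rate=cfg.dropblock_rate, dropblock_size=cfg.dropblock_size,
                dropblock_seed=drop_seed + 1)
        else:
            second = PDCM(BlockConfig(
                in_channels=out_ch, out_channels=out_ch,
                dilation_rates=cfg.dilation_rates, kernel_size=cfg.kernel_size,
                use_previous_branch=(cfg.variant == "pdcm_previous"),
                cam_reduction=cfg.cam_reduction,
                dropblock_rate=cfg.dropblock_rate,
                dropblock_size=cfg.dropblock_size), rng)
        main = Sequential(basic, second)
        self.body = Residual(main, in_ch, out_ch, rng) if cfg.use_residual else main

    def forward(self, x):
        return self.body(x)


class PDCNet(Module):
    """Encoder-decoder lesion segmentation network."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        chs = cfg.channels

        self.encoder = []
        in_ch = cfg.input_channels
        for i, out_ch in enumerate(chs):
            self.encoder.append(_LevelBlock(cfg, in_ch, out_ch, rng, drop_seed=1000 + 10 * i))
            in_ch = out_ch

        self.upconvs = []
        self.decoder = []
        for i in range(cfg.depth - 2, -1, -1):
            self.upconvs.append(ConvTranspose2d(chs[i + 1], chs[i], rng))
            self.decoder.append(
                _LevelBlock(cfg, 2 * chs[i], chs[i], rng, drop_seed=2000 + 10 * i))

        self.head = Conv2d(chs[0], 1, 1, rng)
        self.last_encoder_shapes = None  # spatial sizes recorded per forward

    def forward(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 4 or x.data.shape[1] != self.cfg.input_channels:
            raise ValueError(
                f"expected input of shape (N, {self.cfg.input_channels}, H, W), "
                f"got {x.data.shape}")
        self.cfg.validate_input_size(x.data.shape[2], x.data.shape[3])

        skips = []
        shapes = []
        h = x
        for i, level in enumerate(self.encoder):
            h = level(h)
            shapes.append(h.data.shape[2:])
            if i < self.cfg.depth - 1:
                skips.append(h)
                h = max_pool2x2(h)
        self.last_encoder_shapes = shapes

        for up, level in zip(self.upconvs, self.decoder):
            h = up(h)
            h = concat_channels(skips.pop(), h)
            h = level(h)

        return sigmoid(self.head(h))

    def predict(self, images):
        """Evaluation-mode forward on a (N,1,H,W) or (H,W) array; returns
        the probability map(s) as numpy."""
        arr = np.asarray(images, dtype=np.float64)
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        was_training = self.training
        self.eval()
        try:
            out = self.forward(Tensor(arr)).data[:, 0]
        finally:
            self.train(was_training)
        return out[0] if squeeze else out


def build_model(cfg: ModelConfig) -> PDCNet:
    """Construct the network for a configuration (deterministic in cfg.seed)."""
    return PDCNet(cfg)


def expected_projection_params(cfg: ModelConfig) -> int:
    """Analytic count of the parameters added by residual projection
    shortcuts (bias-free 1x1 convolutions at every channel-changing block)."""
    chs = cfg.channels
    total = 0
    in_ch = cfg.input_channels
    for out_ch in chs:  # encoder levels
        if in_ch != out_ch:
            total += in_ch * out_ch
        in_ch = out_ch
    for i in range(cfg.depth - 2, -1, -1):  # decoder levels: 2c -> c
        total += 2 * chs[i] * chs[i]
    return total


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: PDCNet, extra: dict | None = None):
    """Write weights (.npz) plus a plain-text JSON manifest recording the
    ModelConfig, so checkpoints are self-describing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    manifest = {"model_config": asdict(model.cfg), "extra": extra or {}}
    manifest_path = path.with_suffix(".json")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_checkpoint(path):
    """Rebuild the model recorded in a checkpoint's manifest and load its
    weights.  Returns (model, extra-dict)."""
    path = Path(path)
    manifest_path = path.with_suffix(".json")
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"checkpoint manifest {manifest_path} missing; cannot reconstruct model")
    manifest = json.loads(manifest_path.read_text())
    cfg = ModelConfig(**manifest["model_config"])
    model = build_model(cfg)
    with np.load(path) as sd:
        model.load_state_dict(dict(sd))
    model.eval()
    return model, manifest.get("extra", {})


# ---------------------------------------------------------------------------
# receptive-field probing
# ---------------------------------------------------------------------------

def _probe_extents(module, grid=63, channels=1):
    """Feed a centered impulse through a module in eval mode with
    all-positive weights and identity normalization; return the bounding
    box extent of each returned branch response."""
    for name, p in module.named_parameters():
        if p.data.ndim >= 3:  # convolution kernels -> all-positive
            p.data = np.full_like(p.data, 1.0)
        elif name.endswith("bias"):
            p.data = np.zeros_like(p.data)
    module.eval()
    x = np.zeros((1, channels, grid, grid), dtype=np.float64)
    x[0, :, grid // 2, grid // 2] = 1.0
    if isinstance(module, PDCM):
        _, branches = module(Tensor(x), return_branches=True)
    else:
        branches = [module(Tensor(x))]

    extents = []
    for br in branches:
        resp = np.abs(br.data[0]).sum(axis=0)
        rows = np.where(resp.sum(axis=1) > 1e-12)[0]
        cols = np.where(resp.sum(axis=0) > 1e-12)[0]
        if rows.size == 0:
            extents.append(0)
        else:
            extents.append(int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)))
    return extents


def receptive_field_report(cfg: ModelConfig) -> dict:
    """Per-level, per-branch effective receptive-field extents.

    Each level's second-stage block is probed with a single-pixel
    impulse at the level's native feature resolution; dilated branches
    are probed in their independent-parallel form so the reported
    extents are the pure per-branch scales (k-1)*d + 1.  The
    input-referred extent accounts for the 2**level pooling stride.
    Channel attention acts pointwise in space (its gate is a global
    statistic), so it reports the extent of its spatial input path.
    """
    rng = np.random.default_rng(0)
    report = {}
    for level in range(cfg.depth):
        stride = 2 ** level
        if cfg.variant == "no_pdcm":
            block = _ProbeConv(cfg, rng)
            extents = _probe_extents(block)
        else:
            bc = BlockConfig(
                in_channels=1, out_channels=1,
                dilation_rates=cfg.dilation_rates, kernel_size=cfg.kernel_size,
                use_previous_branch=False, cam_reduction=1,
                dropblock_rate=0.0)
            extents = _probe_extents(PDCM(bc, rng))
        report[level] = {
            "feature_extents": extents,
            "input_extents": [(e - 1) * stride + 1 for e in extents],
            "pool_stride": stride,
        }
    return report


class _ProbeConv(Module):
    """Single plain conv block used to probe the no_pdcm variant."""

    def __init__(self, cfg, rng):
        super().__init__()
        self.unit = BasicConvBlock(1, 1, rng, kernel_size=cfg.kernel_size,
                                   dropblock_rate=0.0)

    def forward(self, x):
        return self.unit(x)
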