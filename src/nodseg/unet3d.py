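"""Three-level 3D U-Net with stage-specific attention.

The enhanced variant places spatial attention after the first two encoder
stages, dilated efficient channel attention after the third (bottleneck)
stage, CBAM in the first and third decoder stages, and squeeze-and-excitation
gates on the 2x-downsampled encoder skip and on the bottleneck feature.  The
baseline variant is the same skeleton with every attention module removed.

At ``base_channels=64`` on a 1x16x96x96 input the per-stage output shapes are

    stem   64 x 16 x 96 x 96
    down1 128 x  8 x 48 x 48   (SA)
    down2 256 x  4 x 24 x 24   (SA)
    down3 512 x  2 x 12 x 12   (Dilated ECA; SE-gated before the decoder)
    up1   256 x  4 x 24 x 24   (CBAM)
    up2   128 x  8 x 48 x 48
    up3    64 x 16 x 96 x 96   (CBAM)
    out     1 x 16 x 96 x 96
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention_blocks import build_attention
from .nn import Tensor, astensor, concatenate, maxpool3d_2, upsample_trilinear_2

VARIANTS = ("baseline", "sa", "sa_eca", "sa_eca_cbam", "enhanced")

_VARIANT_FLAGS = {
    "baseline":     dict(sa=False, eca=False, cbam=False, se=False),
    "sa":           dict(sa=True, eca=False, cbam=False, se=False),
    "sa_eca":       dict(sa=True, eca=True, cbam=False, se=False),
    "sa_eca_cbam":  dict(sa=True, eca=True, cbam=True, se=False),
    "enhanced":     dict(sa=True, eca=True, cbam=True, se=True),
}


@dataclass
class StageSpec:
    in_channels: int
    out_channels: int
    attention: str = "none"     # none | SA | DilatedECA | CBAM
    dropout_rate: float = 0.1


@dataclass
class NetworkConfig:
    base_channels: int = 64
    in_channels: int = 1
    variant: str = "enhanced"
    dropout_rate: float = 0.1
    attention_cfg: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in _VARIANT_FLAGS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    @property
    def flags(self) -> dict:
        return _VARIANT_FLAGS[self.variant]


class DoubleConv3d(nn.Module):
    """Two conv(3^3)-BN-ReLU layers plus a residual connection.

    A 1x1x1 projection (no normalization) carries the residual when the
    channel counts differ; otherwise the input is added directly.
    """

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        self.conv1 = nn.Conv3d(in_channels, out_channels, 3, rng=rng)
        self.bn1 = nn.BatchNorm3d(out_channels)
        self.conv2 = nn.Conv3d(out_channels, out_channels, 3, rng=rng)
        self.bn2 = nn.BatchNorm3d(out_channels)
        if in_channels != out_channels:
            self.proj = nn.Conv3d(in_channels, out_channels, 1, rng=rng)
        else:
            self.proj = nn.Identity()

    def forward(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        return y + self.proj(x)


class DownStage(nn.Module):
    """Max-pool 2x, double conv, optional attention, channel dropout."""

    def __init__(self, spec: StageSpec, attention_cfg=None, rng=None, drop_rng=None):
        super().__init__()
        self.block = DoubleConv3d(spec.in_channels, spec.out_channels, rng=rng)
        self.attention = build_attention(spec.attention, spec.out_channels,
                                         attention_cfg, rng=rng)
        self.dropout = nn.Dropout3d(spec.dropout_rate, rng=drop_rng)

    def forward(self, x):
        d, h, w = x.shape[-3:]
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"down stage needs even spatial dims, got {(d, h, w)}")
        y = self.block(maxpool3d_2(x))
        y = self.attention(y)
        return self.dropout(y)


class UpStage(nn.Module):
    """Trilinear 2x upsample, skip concatenation, double conv, optional CBAM."""

    def __init__(self, spec: StageSpec, attention_cfg=None, rng=None, drop_rng=None):
        super().__init__()
        self.block = DoubleConv3d(spec.in_channels, spec.out_channels, rng=rng)
        self.attention = build_attention(spec.attention, spec.out_channels,
                                         attention_cfg, rng=rng)
        self.dropout = nn.Dropout3d(spec.dropout_rate, rng=drop_rng)

    def forward(self, x, skip):
        up = upsample_trilinear_2(x)
        if up.shape[-3:] != skip.shape[-3:]:
            raise ValueError(
                f"skip shape {tuple(skip.shape)} does not match upsampled "
                f"shape {tuple(up.shape)}")
        y = self.block(concatenate([up, skip], axis=1))
        y = self.attention(y)
        return self.dropout(y)


class AttentionUNet3d(nn.Module):
    """Encoder-decoder segmentation network; ``forward`` returns logits.

    ``forward(..., ledger=list)`` appends (stage, channels-first shape)
    tuples so the per-stage output shapes can be audited.
    """

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        b = cfg.base_channels
        f = cfg.flags
        rng = np.random.default_rng(cfg.seed)
        drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD0]))
        dr = cfg.dropout_rate

        def stage_cfg(channels):
            # clamp channel-gate reductions so width-reduced models build
            out = dict(cfg.attention_cfg)
            out["cbam_reduction"] = min(out.get("cbam_reduction", 16), channels)
            out["se_reduction"] = min(out.get("se_reduction", 16), channels)
            return out
        sa = "SA" if f["sa"] else "none"
        eca = "DilatedECA" if f["eca"] else "none"
        cbam = "CBAM" if f["cbam"] else "none"

        self.stem = DoubleConv3d(cfg.in_channels, b, rng=rng)
        self.down1 = DownStage(StageSpec(b, 2 * b, sa, dr), stage_cfg(2 * b),
                               rng, drop_rng)
        self.down2 = DownStage(StageSpec(2 * b, 4 * b, sa, dr), stage_cfg(4 * b),
                               rng, drop_rng)
        self.down3 = DownStage(StageSpec(4 * b, 8 * b, eca, dr), stage_cfg(8 * b),
                               rng, drop_rng)
        if f["se"]:
            self.se_skip1 = build_attention("SE", 2 * b, stage_cfg(2 * b), rng=rng)
            self.se_bottleneck = build_attention("SE", 8 * b, stage_cfg(8 * b),
                                                 rng=rng)
        else:
            self.se_skip1 = nn.Identity()
            self.se_bottleneck = nn.Identity()
        self.up1 = UpStage(StageSpec(8 * b + 4 * b, 4 * b, cbam, dr),
                           stage_cfg(4 * b), rng, drop_rng)
        self.up2 = UpStage(StageSpec(4 * b + 2 * b, 2 * b, "none", dr),
                           stage_cfg(2 * b), rng, drop_rng)
        self.up3 = UpStage(StageSpec(2 * b + b, b, cbam, dr), stage_cfg(b),
                           rng, drop_rng)
        self.out_conv = nn.Conv3d(b, 1, 1, rng=rng)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, x, ledger: list | None = None):
        x = astensor(x)
        squeeze = x.ndim == 4
        if squeeze:
            x = x.reshape((1,) + x.shape)
        d, h, w = x.shape[-3:]
        if d % 8 or h % 8 or w % 8:
            raise ValueError(
                f"input spatial dims must be divisible by 8, got {(d, h, w)}")

        def log(name, t):
            if ledger is not None:
                ledger.append((name, tuple(t.shape[1:])))

        x0 = self.stem(x); log("stem", x0)
        x1 = self.down1(x0); log("down1", x1)
        x2 = self.down2(x1); log("down2", x2)
        x3 = self.down3(x2); log("down3", x3)
        x3g = self.se_bottleneck(x3); log("se_bottleneck", x3g)
        x1g = self.se_skip1(x1); log("se_skip1", x1g)
        u1 = self.up1(x3g, x2); log("up1", u1)
        u2 = self.up2(u1, x1g); log("up2", u2)
        u3 = self.up3(u2, x0); log("up3", u3)
        logits = self.out_conv(u3); log("out", logits)
        return logits.reshape(logits.shape[1:]) if squeeze else logits

    def shape_ledger(self, input_shape=(1, 16, 96, 96)) -> list:
        """Eval-mode forward on a zero patch, returning the stage shapes."""
        ledger: list = []
        was_training = self.training
        self.eval()
        with nn.no_grad():
            self.forward(np.zeros(input_shape, dtype=np.float32), ledger=ledger)
        self.train(was_training)
        return ledger


def build_model(cfg: NetworkConfig) -> AttentionUNet3d:
    return AttentionUNet3d(cfg)


def expected_stage_shapes(base_channels: int = 64, input_shape=(1, 16, 96, 96)):
    """The per-stage output shapes the architecture is specified to produce."""
    b = base_channels
    _, d, h, w = input_shape
    return [
        ("stem", (b, d, h, w)),
        ("down1", (2 * b, d // 2, h // 2, w // 2)),
        ("down2", (4 * b, d // 4, h // 4, w // 4)),
        ("down3", (8 * b, d // 8, h // 8, w // 8)),
        ("se_bottleneck", (8 * b, d // 8, h // 8, w // 8)),
        ("se_skip1", (2 * b, d // 2, h // 2, w // 2)),
        ("up1", (4 * b, d // 4, h // 4, w // 4)),
        ("up2", (2 * b, d // 2, h // 2, w // 2)),
        ("up3", (b, d, h, w)),
        ("out", (1, d, h, w)),
    ]
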