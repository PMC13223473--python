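"""Attention blocks for volumetric feature maps.

Four mechanisms are provided, each a multiplicative gate on a (C, D, H, W)
feature map (a leading batch axis is accepted and preserved):

* :class:`SpatialAttention3d` — channel-pooled avg/max descriptors, a k^3
  convolution and a sigmoid produce a per-voxel gate in (0, 1).
* :class:`DilatedECA3d` — the channels are split into four groups, each
  filtered by a depthwise-separable convolution at dilation rates 1, 2, 5, 7;
  a 1D convolution with a channel-adaptive kernel over the globally pooled
  descriptor, followed by ReLU then sigmoid, yields a per-channel gate.
  Because the sigmoid sees a ReLU-rectified signal, this gate lives in
  [0.5, 1) — it can only preserve or (mildly) attenuate channels.
* :class:`CBAM3d` — sequential channel gate (shared two-layer MLP over
  spatial avg/max descriptors) then spatial gate (7^3 convolution).
* :class:`SEBlock3d` — squeeze (global average pool) and excite (two fully
  connected layers) per-channel recalibration.

Gates are pure functions of the input given fixed weights; every block
preserves the input shape exactly.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .nn import Tensor, astensor, concatenate


def _with_batch(x):
    """Return (5-d tensor, had_batch) for 4-d or 5-d input."""
    x = astensor(x)
    if x.ndim == 4:
        return x.reshape((1,) + x.shape), False
    if x.ndim == 5:
        return x, True
    raise ValueError(f"expected (C,D,H,W) or (N,C,D,H,W), got shape {x.shape}")


def _debatch(y: Tensor, had_batch: bool) -> Tensor:
    return y if had_batch else y.reshape(y.shape[1:])


def channel_pool_stats(x):
    """Average and maximum over the channel axis.

    Returns a pair of arrays/tensors of shape (1, D, H, W) (plus any leading
    batch axis): the per-voxel channel mean and channel max.
    """
    x5, had_batch = _with_batch(x)
    if x5.shape[1] < 1:
        raise ValueError("channel axis is empty")
    avg = x5.mean(axis=1, keepdims=True)
    mx = x5.max(axis=1, keepdims=True)
    return _debatch(avg, had_batch), _debatch(mx, had_batch)


def dynamic_kernel_size(C: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Channel-adaptive odd kernel size k = |log2(C)/gamma + b/gamma|_odd.

    The nearest odd integer is returned (ties round up, so k grows with C);
    the result is floored at 1.
    """
    if C < 1:
        raise ValueError(f"channel count must be >= 1, got {C}")
    t = math.log2(C) / gamma + b / gamma
    lo = 2 * math.floor((t - 1.0) / 2.0) + 1
    hi = lo + 2
    k = lo if (t - lo) < (hi - t) else hi
    return max(1, int(k))


class SpatialAttention3d(nn.Module):
    """Per-voxel gate from channel-pooled statistics (used in the encoder)."""

    def __init__(self, kernel: int = 7, rng=None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"spatial-attention kernel must be odd, got {kernel}")
        self.conv = nn.Conv3d(2, 1, kernel, rng=rng)

    def attention_map(self, x):
        x5, had_batch = _with_batch(x)
        avg, mx = channel_pool_stats(x5)
        cat = concatenate([avg, mx], axis=1)
        m = self.conv(cat).sigmoid()
        return _debatch(m, had_batch)

    def forward(self, x):
        x5, had_batch = _with_batch(x)
        return _debatch(x5 * self.attention_map(x5), had_batch)


class DilatedECA3d(nn.Module):
    """Multi-scale dilated depthwise-separable convolution with an efficient
    channel-attention gate.

    The channel-interaction kernel and the per-group spatial kernel both use
    the adaptive size psi(C) of the full (pre-split) channel count.
    """

    RATES = (1, 2, 5, 7)

    def __init__(self, channels: int, rates=RATES, gamma: float = 2.0,
                 b: float = 1.0, rng=None):
        super().__init__()
        rates = tuple(rates)
        if channels % len(rates) != 0:
            raise ValueError(
                f"DilatedECA3d requires channels divisible by {len(rates)} "
                f"(one group per dilation rate), got C={channels}")
        self.channels = channels
        self.rates = rates
        self.group_channels = channels // len(rates)
        k = dynamic_kernel_size(channels, gamma, b)
        self.kernel_size = k
        gc = self.group_channels
        for i, d in enumerate(rates):
            setattr(self, f"depthwise{i}",
                    nn.Conv3d(gc, gc, k, dilation=d, groups=gc, rng=rng))
            setattr(self, f"pointwise{i}", nn.Conv3d(gc, gc, 1, rng=rng))
        self.conv1d = nn.Conv1d(1, 1, k, rng=rng)

    def multiscale_conv(self, x):
        """Split into dilation groups, filter each, concatenate (X1..X4 order)."""
        x5, had_batch = _with_batch(x)
        if x5.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x5.shape[1]}")
        gc = self.group_channels
        outs = []
        for i in range(len(self.rates)):
            xi = x5[:, i * gc:(i + 1) * gc]
            yi = getattr(self, f"pointwise{i}")(getattr(self, f"depthwise{i}")(xi))
            outs.append(yi)
        return _debatch(concatenate(outs, axis=1), had_batch)

    def gate(self, x_concat):
        """Channel gate in [0.5, 1): sigmoid(ReLU(conv1d(GAP(x))))."""
        x5, had_batch = _with_batch(x_concat)
        n, c = x5.shape[:2]
        desc = x5.mean(axis=(2, 3, 4))          # (N, C)
        w = self.conv1d(desc.reshape(n, 1, c)).relu().sigmoid()
        w = w.reshape(n, c)
        return w if had_batch else w.reshape(c)

    def forward(self, x):
        x5, had_batch = _with_batch(x)
        xc = self.multiscale_conv(x5)
        w = self.gate(xc)
        y = xc * w.reshape(w.shape + (1, 1, 1))
        return _debatch(y, had_batch)


class CBAM3d(nn.Module):
    """Sequential channel then spatial attention.

    ``gate_mode='summed_logits'`` (default) sums the MLP outputs of the avg
    and max descriptors before a single sigmoid, giving a channel gate in
    (0, 1).  ``gate_mode='per_branch_sigmoid'`` applies a sigmoid to each
    branch and adds the results, giving a gate in (0, 2).
    """

    GATE_MODES = ("summed_logits", "per_branch_sigmoid")

    def __init__(self, channels: int, reduction: int = 16, kernel: int = 7,
                 gate_mode: str = "summed_logits", rng=None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"CBAM spatial kernel must be odd, got {kernel}")
        if channels < reduction:
            raise ValueError(
                f"CBAM reduction {reduction} exceeds channel count {channels}")
        if gate_mode not in self.GATE_MODES:
            raise ValueError(f"gate_mode must be one of {self.GATE_MODES}")
        self.channels = channels
        self.gate_mode = gate_mode
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)
        self.spatial_conv = nn.Conv3d(2, 1, kernel, rng=rng)

    def _mlp(self, desc):
        return self.fc2(self.fc1(desc).relu())

    def channel_gate(self, x):
        """Per-channel weights from spatially pooled avg/max descriptors."""
        x5, had_batch = _with_batch(x)
        avg = x5.mean(axis=(2, 3, 4))
        mx = x5.max(axis=2, keepdims=False).max(axis=2, keepdims=False)
        mx = mx.max(axis=2, keepdims=False)
        if self.gate_mode == "summed_logits":
            gate = (self._mlp(avg) + self._mlp(mx)).sigmoid()
        else:
            gate = self._mlp(avg).sigmoid() + self._mlp(mx).sigmoid()
        return gate if had_batch else gate.reshape(gate.shape[-1])

    def spatial_gate(self, f_c):
        """Per-voxel gate on the channel-refined map."""
        x5, had_batch = _with_batch(f_c)
        avg, mx = channel_pool_stats(x5)
        m = self.spatial_conv(concatenate([avg, mx], axis=1)).sigmoid()
        return _debatch(x5 * m, had_batch)

    def forward(self, x):
        x5, had_batch = _with_batch(x)
        gate = self.channel_gate(x5)
        f_c = x5 * gate.reshape(gate.shape + (1, 1, 1))
        return _debatch(self.spatial_gate(f_c), had_batch)


class SEBlock3d(nn.Module):
    """Squeeze-and-excitation per-channel recalibration."""

    def __init__(self, channels: int, reduction: int = 16, rng=None):
        super().__init__()
        self.channels = channels
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def weights(self, x):
        x5, _ = _with_batch(x)
        desc = x5.mean(axis=(2, 3, 4))
        return self.fc2(self.fc1(desc).relu()).sigmoid()

    def forward(self, x):
        x5, had_batch = _with_batch(x)
        s = self.weights(x5)
        return _debatch(x5 * s.reshape(s.shape + (1, 1, 1)), had_batch)


def build_attention(kind: str, channels: int, cfg: dict | None = None, rng=None):
    """Construct an attention block from a plain config mapping.

    ``kind`` is one of 'none', 'SA', 'DilatedECA', 'CBAM', 'SE'.
    """
    cfg = dict(cfg or {})
    if kind in (None, "none"):
        return nn.Identity()
    if kind == "SA":
        return SpatialAttention3d(kernel=cfg.get("sa_kernel", 7), rng=rng)
    if kind == "DilatedECA":
        return DilatedECA3d(channels, rates=cfg.get("dilation_rates", DilatedECA3d.RATES),
                            gamma=cfg.get("gamma", 2.0), b=cfg.get("b", 1.0), rng=rng)
    if kind == "CBAM":
        return CBAM3d(channels, reduction=cfg.get("cbam_reduction", 16),
                      kernel=cfg.get("cbam_kernel", 7),
                      gate_mode=cfg.get("cbam_gate_mode", "summed_logits"), rng=rng)
    if kind == "SE":
        return SEBlock3d(channels, reduction=cfg.get("se_reduction", 16), rng=rng)
    raise ValueError(f"unknown attention kind {kind!r}")
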