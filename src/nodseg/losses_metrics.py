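"""Composite segmentation loss and voxel-overlap evaluation metrics.

The training loss is a convex combination of three terms computed on sigmoid
probabilities:

    L = w1 * L_BCE(alpha) + w2 * L_Dice + w3 * L_IoU,   w1 + w2 + w3 = 1

where the binary cross-entropy weights positive (nodule) voxels by ``alpha``
to counter the extreme class imbalance (positive voxels are well under 1% of
a patch), the Dice term optimizes soft overlap, and the IoU term penalizes
union mismatch.  Evaluation metrics (DSC, sensitivity, precision) are
computed on hard masks thresholded at 0.5.

Loss functions accept plain arrays (returning floats) or autodiff tensors
(returning scalar tensors for backprop).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Tensor, astensor

#: Loss mixture found by the swarm search at full scale, and the positive
#: class weight used with it.
DEFAULT_WEIGHTS = (0.2093, 0.4702, 0.3205)
DEFAULT_ALPHA = 1.56
DEFAULT_EPSILON = 1e-5

_CLAMP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Simplex-constrained mixture (w_bce, w_dice, w_iou) plus BCE class weight."""

    w_bce: float = DEFAULT_WEIGHTS[0]
    w_dice: float = DEFAULT_WEIGHTS[1]
    w_iou: float = DEFAULT_WEIGHTS[2]
    alpha: float = DEFAULT_ALPHA
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        s = self.w_bce + self.w_dice + self.w_iou
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"loss weights must sum to 1 (got {s:.8f})")
        if min(self.w_bce, self.w_dice, self.w_iou) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def _prepare(prob, target):
    was_array = not isinstance(prob, Tensor)
    prob = astensor(prob)
    target = astensor(target).data  # targets never need gradients
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs target {target.shape}")
    return prob, target, was_array


def _ret(loss: Tensor, was_array: bool):
    return loss.item() if was_array else loss


def weighted_bce(prob, target, alpha: float = DEFAULT_ALPHA):
    """Mean over voxels of -[alpha*y*log(p) + (1-y)*log(1-p)].

    Probabilities outside the open unit interval are clamped to
    [1e-7, 1-1e-7] with a warning.
    """
    prob, target, was_array = _prepare(prob, target)
    if prob.data.min() < _CLAMP or prob.data.max() > 1.0 - _CLAMP:
        warnings.warn("probabilities clamped to [1e-7, 1-1e-7] for BCE",
                      RuntimeWarning, stacklevel=2)
    p = prob.clip(_CLAMP, 1.0 - _CLAMP)
    loss = -(alpha * target * p.log() + (1.0 - target) * (1.0 - p).log()).mean()
    return _ret(loss, was_array)


def dice_loss(prob, target, epsilon: float = DEFAULT_EPSILON):
    """1 - (2*sum(p*y) + eps) / (sum(p) + sum(y) + eps) on soft probabilities."""
    prob, target, was_array = _prepare(prob, target)
    inter = (prob * target).sum()
    denom = prob.sum() + float(target.sum())
    loss = 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)
    return _ret(loss, was_array)


def iou_loss(prob, target, epsilon: float = DEFAULT_EPSILON):
    """1 - (I + eps) / (U + eps) with U = sum(p) + sum(y) - I."""
    prob, target, was_array = _prepare(prob, target)
    inter = (prob * target).sum()
    union = prob.sum() + float(target.sum()) - inter
    loss = 1.0 - (inter + epsilon) / (union + epsilon)
    return _ret(loss, was_array)


def combined_loss(prob, target, lw: LossWeights = LossWeights()):
    """w_bce*BCE + w_dice*Dice + w_iou*IoU (weights on the unit simplex)."""
    prob2, target2, was_array = _prepare(prob, target)
    loss = (lw.w_bce * weighted_bce(prob2, target2, lw.alpha)
            + lw.w_dice * dice_loss(prob2, target2, lw.epsilon)
            + lw.w_iou * iou_loss(prob2, target2, lw.epsilon))
    return _ret(loss, was_array)


def combined_loss_with_logits(logits, target, lw: LossWeights = LossWeights()):
    """Fused sigmoid + combined loss on logits, with an analytic gradient.

    Numerically identical to ``combined_loss(sigmoid(logits), target)`` but
    taped as a single operation, which avoids a dozen full-volume
    intermediates per training step.  ``logits`` must be a tensor.
    """
    from .nn import Tensor

    if not isinstance(logits, Tensor):
        raise TypeError("combined_loss_with_logits expects a logits tensor")
    z = logits.data
    y = astensor(target).data
    if z.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {z.shape} vs target {y.shape}")
    p = np.empty_like(z)
    pos = z >= 0
    p[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    p[~pos] = ez / (1.0 + ez)

    n = p.size
    pc = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    bce = -(lw.alpha * y * np.log(pc) + (1.0 - y) * np.log1p(-pc)).mean()
    sy = float(y.sum())
    sp = float(p.sum())
    inter = float((p * y).sum())
    eps = lw.epsilon
    dice = 1.0 - (2.0 * inter + eps) / (sp + sy + eps)
    union = sp + sy - inter
    iou = 1.0 - (inter + eps) / (union + eps)
    value = lw.w_bce * bce + lw.w_dice * dice + lw.w_iou * iou

    from .nn.autograd import _make
    out = _make(np.float32(value), (logits,))
    if out._prev:
        def bwd(g, logits=logits, p=p, y=y, lw=lw, n=n, sp=sp, sy=sy,
                inter=inter, eps=eps, union=union):
            scale = float(g)
            # BCE gradient wrt logits (clamped voxels contribute zero)
            inwin = (p >= _CLAMP) & (p <= 1.0 - _CLAMP)
            gz = (-(lw.alpha * y * (1.0 - p) - (1.0 - y) * p) / n) * inwin
            gz *= lw.w_bce
            # soft Dice and IoU gradients wrt probabilities
            denom_d = (sp + sy + eps) ** 2
            gp = lw.w_dice * (-(2.0 * y * (sp + sy + eps)
                                - (2.0 * inter + eps)) / denom_d)
            denom_u = (union + eps) ** 2
            gp += lw.w_iou * (-(y * (union + eps)
                                - (inter + eps) * (1.0 - y)) / denom_u)
            gz += gp * p * (1.0 - p)
            logits._accum_own((scale * gz).astype(np.float32))
        out._backward = bwd
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred_binary, target) -> ConfusionCounts:
    p = np.asarray(pred_binary).astype(bool)
    t = np.asarray(target).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def segmentation_metrics(pred_binary, target) -> tuple[float, float, float]:
    """(DSC, SEN, PPV) on hard masks.

    Degenerate conventions: with an empty target, SEN = 1 if the prediction
    is also empty else 0 (and symmetrically for PPV with an empty
    prediction); DSC = 1 when both masks are empty.  These cases arise
    routinely on nodule-free patches.
    """
    c = confusion_counts(pred_binary, target)
    if c.tp + c.fn == 0:
        sen = 1.0 if c.fp == 0 else 0.0
    else:
        sen = c.tp / (c.tp + c.fn)
    if c.tp + c.fp == 0:
        ppv = 1.0 if c.fn == 0 else 0.0
    else:
        ppv = c.tp / (c.tp + c.fp)
    if 2 * c.tp + c.fp + c.fn == 0:
        dsc = 1.0
    else:
        dsc = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return dsc, sen, ppv
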