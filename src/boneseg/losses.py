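"""Training losses: weighted BCE, soft centerline-Dice, and their schedule.

The compound loss warms up on weighted binary cross-entropy alone (the
positive class up-weighted to counter the extreme foreground/background
imbalance of thin curves), then linearly blends in a differentiable
centerline-Dice loss until the two contribute 50:50 at the final epoch.

The soft clDice loss replaces hard morphological skeletons by iterated
soft erosion (min-pooling) and soft dilation (max-pooling) of the
probability map, which keeps the topology precision/sensitivity terms
differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import functional as F
from .nn.autodiff import (Tensor, add, as_tensor, div, minimum, mul, relu,
                          sub, tsum)


@dataclass(frozen=True)
class LossSchedule:
    warmup_epochs: int = 10
    pos_weight: float = 20.0
    final_cl_weight: float = 0.5
    total_epochs: int = 60
    ramp: str = "linear"          # "linear" | "cosine"

    def __post_init__(self):
        if not 0 < self.warmup_epochs < self.total_epochs:
            raise ValueError("need 0 < warmup_epochs < total_epochs")
        if not 0.0 <= self.final_cl_weight <= 1.0:
            raise ValueError("final_cl_weight must be in [0, 1]")
        if self.ramp not in ("linear", "cosine"):
            raise ValueError("ramp must be 'linear' or 'cosine'")


@dataclass(frozen=True)
class SoftSkeletonParams:
    n_iterations: int = 10
    epsilon: float = 1e-6

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def blend_weights(epoch: int, schedule: LossSchedule) -> tuple[float, float]:
    """Per-epoch (w_wbce, w_cl); epochs are 1-based.

    Epochs 1..warmup are pure WBCE; the clDice weight then ramps from 0 to
    ``final_cl_weight`` at the last epoch, and the weights always sum to 1.
    """
    if not 1 <= epoch <= schedule.total_epochs:
        raise ValueError(f"epoch {epoch} outside 1..{schedule.total_epochs}")
    if epoch <= schedule.warmup_epochs:
        return 1.0, 0.0
    frac = (epoch - schedule.warmup_epochs) / (
        schedule.total_epochs - schedule.warmup_epochs)
    if schedule.ramp == "cosine":
        frac = 0.5 * (1.0 - np.cos(np.pi * frac))
    w_cl = schedule.final_cl_weight * frac
    return 1.0 - w_cl, w_cl


def wbce_loss(logits, target, pos_weight=20.0):
    """Mean pixel-wise BCE on logits with positive-class weight."""
    return F.weighted_bce_with_logits(as_tensor(logits), target, pos_weight)


def _soft_erode(img):
    return minimum(F.pool3(img, 2, "min"), F.pool3(img, 3, "min"))


def _soft_dilate(img):
    return F.pool3(F.pool3(img, 2, "max"), 3, "max")


def _soft_open(img):
    return _soft_dilate(_soft_erode(img))


def soft_skeleton(probs, n_iterations=10):
    """Differentiable skeleton of a probability map via iterated soft morphology.

    Each round erodes the map and accumulates the ridge residue
    ``relu(img - open(img))``; after enough rounds the residue approximates
    a 1-px-wide soft centerline.
    """
    img = as_tensor(probs)
    skel = relu(sub(img, _soft_open(img)))
    for _ in range(n_iterations):
        img = _soft_erode(img)
        delta = relu(sub(img, _soft_open(img)))
        # skel = skel + delta*(1 - skel) : accumulate without double counting
        skel = sub(add(skel, delta), mul(skel, delta))
    return skel


def soft_cldice_loss(probs, target, params: SoftSkeletonParams | None = None):
    """1 - soft clDice between a probability map and a binary target.

    ``probs`` in [0, 1], any leading batch/channel axes; ``target`` is a
    binary array of the same shape.  Finite for empty targets thanks to the
    epsilon smoothing (both-empty inputs give loss ~0).
    """
    params = params or SoftSkeletonParams()
    probs = as_tensor(probs)
    t = np.asarray(target, dtype=probs.data.dtype)
    if t.shape != probs.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {t.shape}")
    tt = Tensor(t)
    eps = params.epsilon
    skel_p = soft_skeleton(probs, params.n_iterations)
    skel_l = soft_skeleton(tt, params.n_iterations)
    tprec = div(tsum(mul(skel_p, tt)) + eps, tsum(skel_p) + eps)
    tsens = div(tsum(mul(skel_l, probs)) + eps, tsum(skel_l) + eps)
    cl = div(mul(mul(tprec, tsens), 2.0), tprec + tsens)
    return sub(Tensor(np.asarray(1.0, dtype=probs.data.dtype)), cl)


class CombinedLoss:
    """Schedule-blended WBCE + soft clDice on logits."""

    def __init__(self, schedule: LossSchedule | None = None,
                 skeleton: SoftSkeletonParams | None = None):
        self.schedule = schedule or LossSchedule()
        self.skeleton = skeleton or SoftSkeletonParams()

    def __call__(self, logits, target, epoch: int):
        from .nn.autodiff import add, sigmoid
        w_wbce, w_cl = blend_weights(epoch, self.schedule)
        loss = mul(wbce_loss(logits, target, self.schedule.pos_weight), w_wbce)
        if w_cl > 0.0:
            probs = sigmoid(as_tensor(logits))
            loss = add(loss, mul(soft_cldice_loss(probs, target, self.skeleton),
                                 w_cl))
        return loss
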