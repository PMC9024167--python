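"""Training utilities: Dice + BCE loss, Adam, and a small full-batch trainer."""

from __future__ import annotations

import numpy as np

from ..metrics import dice as dice_coefficient
from .autodiff import Tensor, bce_with_logits
from .model import UNet

__all__ = ["Adam", "dice_bce_loss", "train_network", "segment_image"]

_EPS = 1e-7


class Adam:
    """Adam optimizer over a list of autodiff tensors."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def dice_bce_loss(
    prob: Tensor, target: np.ndarray, smooth: float = 1.0, logits: Tensor | None = None
) -> Tensor:
    """Soft-Dice loss plus binary cross-entropy against a {0,1} target.

    When the pre-sigmoid ``logits`` are supplied the BCE term is computed
    from them (stable, non-vanishing gradient in the saturated regime).
    """
    y = np.asarray(target, dtype=float)
    inter = (prob * y).sum()
    dice_loss = 1.0 - (2.0 * inter + smooth) / (prob.sum() + float(y.sum()) + smooth)
    if logits is not None:
        bce = bce_with_logits(logits, y)
    else:
        bce = -(
            Tensor(y) * (prob + _EPS).log() + Tensor(1.0 - y) * (1.0 - prob + _EPS).log()
        ).mean()
    return dice_loss + bce


def _downscale_mask(mask: np.ndarray, times: int) -> np.ndarray:
    """Max-pool a binary mask ``times`` times (foreground-preserving)."""
    out = mask.astype(float)
    for _ in range(times):
        slices = tuple(slice(0, (s // 2) * 2) for s in out.shape)
        out = out[slices]
        for ax in range(out.ndim):
            shape = list(out.shape)
            shape[ax] //= 2
            shape.insert(ax + 1, 2)
            out = out.reshape(shape).max(axis=ax + 1)
    return out


def train_network(
    net: UNet,
    images: np.ndarray,
    masks: np.ndarray,
    steps: int = 300,
    lr: float = 3e-3,
    aux_weight: float = 0.5,
    log_every: int = 10,
) -> list[dict]:
    """Full-batch Adam training; returns a history of (step, loss, dice) records.

    ``images``/``masks`` are (N, H, W) (or (N, D, H, W) for 3D nets).
    Dice is evaluated on the 0.5-thresholded probability map.
    """
    imgs = np.asarray(images, dtype=float)[:, None]
    y = np.asarray(masks, dtype=float)[:, None]
    opt = Adam(net.parameters(), lr=lr)
    history: list[dict] = []
    for step in range(1, steps + 1):
        x = Tensor(imgs)
        logit, aux_logits = net.forward_logits(x)
        prob = logit.sigmoid()
        loss = dice_bce_loss(prob, y, logits=logit)
        for k, aux_logit in enumerate(aux_logits):
            times = len(net.up_convs) - 1 - k
            y_small = np.stack([_downscale_mask(m[0], times) for m in y])[:, None]
            loss = loss + aux_weight * dice_bce_loss(aux_logit.sigmoid(), y_small, logits=aux_logit)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if step % log_every == 0 or step == steps or step == 1:
            d = dice_coefficient(y[:, 0] > 0.5, prob.data[:, 0] >= 0.5)
            history.append({"step": step, "loss": float(loss.data), "dice": float(d)})
    return history


def segment_image(net: UNet, image: np.ndarray, threshold: float = 0.5):
    """Probability map and thresholded mask for one image."""
    prob = net.predict(image)
    return prob, (prob >= threshold).astype(np.uint8)
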