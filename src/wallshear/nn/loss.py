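"""Composite training loss: component MAE + SSIM pattern term + L2.

    loss = l_MAE + omega * l_SSIM + (lambda / 2m) * sum(w^2)

l_MAE is the mean absolute error over valid pixels of each predicted WSS
vector component. l_SSIM = 1 - SSIM between the predicted and true WSS
*magnitude* images (masked pixels zeroed in both), rewarding pattern
similarity. The L2 term sums squared convolution weights, scaled by the
regularization weight lambda over twice the batch size m.

SSIM follows the standard luminance/contrast/structure decomposition over
uniform 11 x 11 local windows,

    l = (2 mx my + C1) / (mx^2 + my^2 + C1)
    c = (2 sx sy + C2) / (sx^2 + sy^2 + C2)
    s = (sxy + C3) / (sx sy + C3)

with C1 = (K1 L)^2, C2 = (K2 L)^2, C3 = C2 / 2, K1 = 0.01, K2 = 0.03, and L
the maximum true WSS within the patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor


@dataclass
class SSIMConfig:
    k1: float = 0.01
    k2: float = 0.03
    window: int = 11
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0


def ssim(x: Tensor | np.ndarray, y: Tensor | np.ndarray, data_range: float,
         config: SSIMConfig | None = None) -> Tensor:
    """Mean SSIM over uniform local windows; differentiable.

    ``x``, ``y``: (B, H, W) or (H, W) images; ``data_range`` is L (> 0).
    Returns a scalar Tensor in (-1, 1].
    """
    cfg = config or SSIMConfig()
    if data_range <= 0:
        raise ValueError("data_range (max true WSS in the patch) must be positive")
    x = x if isinstance(x, Tensor) else Tensor(x)
    y = y if isinstance(y, Tensor) else Tensor(y)
    if x.ndim == 2:
        x = x.reshape(1, *x.shape)
        y = y.reshape(1, *y.shape)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    b, h, w = x.shape
    win = cfg.window
    if h < win or w < win:
        raise ValueError(f"images smaller than the {win}x{win} SSIM window")
    c1 = (cfg.k1 * data_range) ** 2
    c2 = (cfg.k2 * data_range) ** 2
    c3 = c2 / 2.0

    def local_mean(img: Tensor) -> Tensor:
        return img.box_mean_valid(win)

    mx = local_mean(x)
    my = local_mean(y)
    mxx = local_mean(x * x)
    myy = local_mean(y * y)
    mxy = local_mean(x * y)
    # unbiased (n/(n-1)) variance/covariance over each window
    n = win * win
    corr = n / (n - 1.0)
    vx = (mxx - mx * mx) * corr
    vy = (myy - my * my) * corr
    cov = (mxy - mx * my) * corr

    lum = (mx * my * 2.0 + c1) / (mx * mx + my * my + c1)
    if cfg.alpha == cfg.beta == cfg.gamma == 1.0:
        # with C3 = C2/2 the contrast and structure terms collapse to
        # (2 sxy + C2) / (sx^2 + sy^2 + C2); avoids sqrt entirely
        smap = lum * ((cov * 2.0 + c2) / (vx + vy + c2))
    else:
        eps = 1e-12  # guards sqrt at zero-variance windows
        sx = (vx.relu() + eps).sqrt()
        sy = (vy.relu() + eps).sqrt()
        con = (sx * sy * 2.0 + c2) / (vx.relu() + vy.relu() + c2)
        struct = (cov + c3) / (sx * sy + c3)
        smap = lum**cfg.alpha * con**cfg.beta * struct**cfg.gamma
    return smap.mean()


@dataclass
class LossConfig:
    omega: float = 1.5
    weight_decay: float = 1e-2  # lambda
    batch_size: int = 16  # m
    ssim: SSIMConfig | None = None


def masked_mae(pred: Tensor, truth: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean absolute error of WSS components over valid pixels."""
    n_valid = mask.sum()
    if n_valid == 0:
        raise ValueError("empty valid mask")
    m3 = mask[..., None].astype(float)
    diff = (pred - Tensor(truth)) * Tensor(m3)
    return diff.abs().sum() * (1.0 / (3.0 * n_valid))


def magnitude_image(x: Tensor, mask: np.ndarray) -> Tensor:
    """Per-pixel vector norm with masked pixels forced to zero."""
    m3 = mask[..., None].astype(float)
    xm = x * Tensor(m3)
    return ((xm * xm).sum(axis=-1) + 1e-12).sqrt() * Tensor(mask.astype(float))


def composite_loss(
    pred: Tensor,
    truth: np.ndarray,
    mask: np.ndarray,
    weights: list[Tensor],
    config: LossConfig | None = None,
) -> tuple[Tensor, dict]:
    """Full training loss on a batch of (B, 48, 48, 3) WSS patches.

    Returns the scalar loss Tensor and a dict of detached term values.
    SSIM is computed on the masked magnitude images with L = max true WSS in
    the batch; batches with zero true WSS skip the SSIM term.
    """
    cfg = config or LossConfig()
    truth = np.asarray(truth, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"pred {pred.shape} vs truth {truth.shape}")
    l_mae = masked_mae(pred, truth, mask)

    # same masked-magnitude computation for both images so that
    # pred == truth gives bitwise-identical operands and SSIM exactly 1
    truth_mag = magnitude_image(Tensor(truth), mask).data
    data_range = float(np.linalg.norm(truth * mask[..., None], axis=-1).max())
    if cfg.omega > 0 and data_range > 0:
        pred_mag = magnitude_image(pred, mask)
        s = ssim(pred_mag, Tensor(truth_mag), data_range, cfg.ssim)
        l_ssim = 1.0 - s
    else:
        l_ssim = Tensor(0.0)

    if cfg.weight_decay > 0 and weights:
        l2 = (weights[0] * weights[0]).sum()
        for wt in weights[1:]:
            l2 = l2 + (wt * wt).sum()
        l2 = l2 * (cfg.weight_decay / (2.0 * cfg.batch_size))
    else:
        l2 = Tensor(0.0)

    total = l_mae + l_ssim * cfg.omega + l2
    terms = {
        "mae": float(l_mae.data),
        "ssim": float(l_ssim.data) if isinstance(l_ssim, Tensor) else float(l_ssim),
        "l2": float(l2.data),
        "total": float(total.data),
    }
    return total, terms
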