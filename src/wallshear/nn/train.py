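"""Patch sampling, augmentation, and the training loop."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ..flatmap import assemble_input
from ..synthetic import FlowCase, FlowSample
from .autodiff import Tensor
from .layers import Adam, cosine_annealing_lr
from .loss import LossConfig, composite_loss
from .unet import PATCH, NetConfig, WSSNet

logger = logging.getLogger(__name__)

COORD_SLICES = (slice(0, 3), slice(3, 6), slice(6, 9))
VEL_SLICES = (slice(9, 12), slice(12, 15))


@dataclass
class TrainingSample:
    """One 48 x 48 training patch: 15-channel input, 3-channel WSS label,
    shared validity mask."""

    inputs: np.ndarray
    label: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.inputs.shape[-1] != 15 or self.label.shape[-1] != 3:
            raise ValueError("expected 15 input channels and 3 label channels")


@dataclass
class AugmentConfig:
    """Stochastic training augmentations.

    Sheet-pair choice and the longitudinal sliding window are part of patch
    extraction; rotation acts on coordinate and vector channels alike;
    translation moves a random node to the origin (coordinates only);
    rolling-shift wraps the circumferential axis by at most 5 pixels; noise
    is Gaussian-smoothed Gaussian with SD drawn from 1-4% of venc.
    """

    rotate: bool = True
    translate: bool = True
    max_roll: int = 5
    noise_prob: float = 0.5
    noise_sd_range: tuple[float, float] = (0.01, 0.04)
    noise_smooth_sigma: float = 1.0
    venc: float = 1.5


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def center_coordinates(inputs: np.ndarray) -> np.ndarray:
    """Subtract the mean wall coordinate from all coordinate channels.

    WSS depends only on relative geometry, so every patch is canonically
    centered; the random-origin translation augmentation then perturbs around
    this canonical frame. Applied identically at training and inference.
    """
    out = inputs.copy()
    origin = out[..., 0:3].mean(axis=(-3, -2), keepdims=True)
    for sl in COORD_SLICES:
        out[..., sl] -= origin
    return out


def extract_patch(frame: FlowSample, v0: int, d1: float, d2: float) -> TrainingSample:
    """Assemble the 15-channel input for one window position and sheet pair."""
    fm = assemble_input(
        frame.wall,
        frame.inner[d1],
        frame.inner[d2],
        frame.sheets[d1],
        frame.sheets[d2],
        extra_mask=frame.mask,
    )
    sl = slice(v0, v0 + PATCH)
    return TrainingSample(
        inputs=center_coordinates(fm.values[:, sl, :]),
        label=frame.label.values[:, sl, :].copy(),
        mask=(fm.mask & frame.label.mask)[:, sl].copy(),
    )


def augment(sample: TrainingSample, cfg: AugmentConfig, rng: np.random.Generator) -> TrainingSample:
    """Apply rotation / translation / rolling-shift / noise to one patch."""
    x = sample.inputs.copy()
    y = sample.label.copy()
    m = sample.mask.copy()

    if cfg.translate:
        u = rng.integers(0, x.shape[0])
        v = rng.integers(0, x.shape[1])
        origin = x[u, v, 0:3].copy()
        for sl in COORD_SLICES:
            x[:, :, sl] -= origin

    if cfg.rotate:
        rot = random_rotation(rng)
        for sl in COORD_SLICES + VEL_SLICES:
            x[:, :, sl] = x[:, :, sl] @ rot.T
        y = y @ rot.T

    if cfg.max_roll > 0:
        k = int(rng.integers(-cfg.max_roll, cfg.max_roll + 1))
        x = np.roll(x, k, axis=0)
        y = np.roll(y, k, axis=0)
        m = np.roll(m, k, axis=0)

    if cfg.noise_prob > 0 and rng.random() < cfg.noise_prob:
        sd = rng.uniform(*cfg.noise_sd_range) * cfg.venc
        for sl in VEL_SLICES:
            noise = rng.normal(0.0, sd, size=x[:, :, sl].shape)
            noise = gaussian_filter(noise, sigma=cfg.noise_smooth_sigma, axes=(0, 1))
            x[:, :, sl] += noise

    return TrainingSample(inputs=x, label=y, mask=m)


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    lr_max: float = 1e-4
    lr_min: float = 1e-7
    lr_cycle: int = 10
    omega: float = 1.5
    weight_decay: float = 1e-2
    seed: int = 0
    patches_per_epoch: int = 512
    # when set, a fixed pool of this many augmented patches is drawn once and
    # iterated per epoch (bounded-data regime); otherwise patches are drawn
    # freshly every step
    patch_pool: int | None = None
    # restrict the sheet-pair (distance-to-wall) augmentation to these
    # (d1, d2) pairs; None draws random pairs from all available distances
    sheet_pairs: list | None = None
    augment: AugmentConfig = field(default_factory=AugmentConfig)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)


def _frame_weights(case: FlowCase) -> np.ndarray:
    """Sampling weights proportional to each frame's mean WSS magnitude.

    Pulsatile series spend most of the cycle in low-flow diastole; weighting
    by |WSS| balances the training pool across the dynamic range so systolic
    magnitudes are not under-represented.
    """
    w = np.array(
        [np.linalg.norm(f.label.values, axis=2)[f.mask].mean() for f in case.frames]
    )
    total = w.sum()
    return w / total if total > 0 else np.full(len(w), 1.0 / len(w))


def _sample_batch(cases: list[FlowCase], size: int, cfg: TrainConfig,
                  rng: np.random.Generator) -> TrainingSample:
    weights = [_frame_weights(c) for c in cases]
    xs, ys, ms = [], [], []
    while len(xs) < size:
        ci = rng.integers(len(cases))
        case = cases[ci]
        frame = case.frames[rng.choice(len(case.frames), p=weights[ci])]
        if cfg.sheet_pairs is not None:
            d1, d2 = cfg.sheet_pairs[rng.integers(len(cfg.sheet_pairs))]
        else:
            dists = sorted(frame.sheets.keys())
            i, j = sorted(rng.choice(len(dists), size=2, replace=False))
            d1, d2 = dists[i], dists[j]
        v0 = int(rng.integers(0, frame.wall.shape[1] - PATCH + 1))
        s = extract_patch(frame, v0, d1, d2)
        s = augment(s, cfg.augment, rng)
        if s.mask.sum() == 0:
            continue
        xs.append(s.inputs)
        ys.append(s.label)
        ms.append(s.mask)
    return TrainingSample(
        inputs=np.stack(xs), label=np.stack(ys), mask=np.stack(ms)
    )


def _val_batches(cases: list[FlowCase], cfg: TrainConfig) -> list[TrainingSample]:
    """Deterministic validation patches: both window extremes, mid sheets."""
    batches = []
    for case in cases:
        for frame in case.frames[:: max(1, len(case.frames) // 4)]:
            dists = sorted(frame.sheets.keys())
            if cfg.sheet_pairs is not None:
                d1, d2 = cfg.sheet_pairs[0]
            else:
                d1, d2 = dists[0], dists[-1]
            nv = frame.wall.shape[1]
            for v0 in (0, nv - PATCH):
                batches.append(extract_patch(frame, v0, d1, d2))
    xs = np.stack([b.inputs for b in batches])
    ys = np.stack([b.label for b in batches])
    ms = np.stack([b.mask for b in batches])
    return [TrainingSample(xs, ys, ms)]


def train(
    train_cases: list[FlowCase],
    val_cases: list[FlowCase] | None = None,
    net_config: NetConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[WSSNet, TrainHistory]:
    """Train the estimator on synthetic flow cases.

    Adam with cosine-annealed learning rate (cycle ``lr_cycle`` epochs between
    ``lr_max`` and ``lr_min``); composite MAE + SSIM + L2 loss. Aborts on
    NaN loss. Deterministic for a fixed seed.
    """
    if not train_cases:
        raise ValueError("empty training set")
    cfg = train_config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    model = WSSNet(net_config)
    loss_cfg = LossConfig(
        omega=cfg.omega, weight_decay=cfg.weight_decay, batch_size=cfg.batch_size
    )
    conv_weights = [
        m.weight for m in model.modules() if hasattr(m, "weight")
    ]
    opt = Adam(model.parameters(), lr=cfg.lr_max)
    history = TrainHistory()
    val = _val_batches(val_cases, cfg) if val_cases else None

    pool: TrainingSample | None = None
    if cfg.patch_pool is not None:
        pool = _sample_batch(train_cases, cfg.patch_pool, cfg, rng)
        steps = max(1, cfg.patch_pool // cfg.batch_size)
    else:
        steps = max(1, cfg.patches_per_epoch // cfg.batch_size)

    for epoch in range(cfg.epochs):
        lr = cosine_annealing_lr(epoch, cfg.lr_cycle, cfg.lr_max, cfg.lr_min)
        opt.lr = lr
        model.train()
        epoch_loss = 0.0
        order = rng.permutation(cfg.patch_pool) if pool is not None else None
        for step_i in range(steps):
            if pool is not None:
                sel = order[step_i * cfg.batch_size : (step_i + 1) * cfg.batch_size]
                batch = TrainingSample(
                    inputs=pool.inputs[sel], label=pool.label[sel], mask=pool.mask[sel]
                )
            else:
                batch = _sample_batch(train_cases, cfg.batch_size, cfg, rng)
            opt.zero_grad()
            pred = model(Tensor(batch.inputs))
            loss, terms = composite_loss(
                pred, batch.label, batch.mask, conv_weights, loss_cfg
            )
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r}, terms={terms}"
                )
            loss.backward()
            opt.step()
            epoch_loss += terms["total"]
        history.train_loss.append(epoch_loss / steps)
        history.lr.append(lr)
        if val is not None:
            model.eval()
            vloss = 0.0
            for vb in val:
                pred = model(Tensor(vb.inputs))
                _, terms = composite_loss(
                    pred, vb.label, vb.mask, [], LossConfig(omega=cfg.omega, weight_decay=0.0)
                )
                vloss += terms["total"]
            history.val_loss.append(vloss / len(val))
            logger.info(
                "epoch %d: lr=%.2e train=%.4f val=%.4f",
                epoch, lr, history.train_loss[-1], history.val_loss[-1],
            )
        else:
            logger.info("epoch %d: lr=%.2e train=%.4f", epoch, lr, history.train_loss[-1])

    calibrate_batchnorm(model, train_cases, cfg)
    return model, history


def calibrate_batchnorm(model: WSSNet, cases: list[FlowCase], cfg: TrainConfig,
                        n_batches: int = 24) -> None:
    """Re-estimate batch-norm inference statistics with a deterministic sweep.

    Runs training-mode forwards over non-augmented patches drawn from the
    training cases, accumulating exact global activation moments per channel.
    """
    from .layers import BatchNorm

    rng = np.random.default_rng(cfg.seed + 1)
    plain = AugmentConfig(rotate=False, translate=False, max_roll=0, noise_prob=0.0)
    sweep_cfg = TrainConfig(
        batch_size=cfg.batch_size, seed=cfg.seed, augment=plain,
        sheet_pairs=cfg.sheet_pairs,
    )
    bns = [m for m in model.modules() if isinstance(m, BatchNorm)]
    for bn in bns:
        bn.start_calibration()
    model.train()
    for _ in range(n_batches):
        batch = _sample_batch(cases, cfg.batch_size, sweep_cfg, rng)
        model(Tensor(batch.inputs))
    for bn in bns:
        bn.finish_calibration()
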