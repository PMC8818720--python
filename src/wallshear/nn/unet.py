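"""Patch-based convolutional WSS estimator.

U-Net-style encoder/decoder over 48 x 48 flatmap patches: 15 input channels
(wall coordinates, two inner-surface coordinate maps, two velocity sheets),
3 output channels (Cartesian WSS vector, Pa). Three encoder and three decoder
blocks of two ReLU convolutions each, batch-normalized at the block end;
max-pool downsampling, bilinear upsampling with skip concatenation. All
convolutions pad periodically along the circumferential axis (the tube is
closed) and replicate edges along the open longitudinal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..flatmap import Flatmap
from .autodiff import Tensor
from .layers import BatchNorm, Conv2d, Module

PATCH = 48


@dataclass
class NetConfig:
    in_channels: int = 15
    out_channels: int = 3
    filters: tuple[int, int, int] = (64, 128, 256)
    patch: int = PATCH
    seed: int = 0
    # fixed per-channel input scaling: coordinates are in mm (tens to
    # hundreds), velocities in m/s (order 1); scaling the nine coordinate
    # channels to decimeters puts all inputs on a comparable dynamic range
    coord_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.patch != PATCH:
            raise ValueError(f"patch edge must equal the template circumference ({PATCH})")


def reduced_config(seed: int = 0) -> NetConfig:
    """Small-filter configuration (~32k parameters) for CPU-scale training."""
    return NetConfig(filters=(8, 16, 32), seed=seed)


class _Block(Module):
    def __init__(self, cin: int, cout: int, pad_mode: str, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, pad_mode=pad_mode, rng=rng)
        self.conv2 = Conv2d(cout, cout, pad_mode=pad_mode, rng=rng)
        self.bn = BatchNorm(cout)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        return self.bn(x)


class WSSNet(Module):
    """Flatmap-patch to WSS-patch regressor."""

    def __init__(self, config: NetConfig | None = None):
        self.config = config or NetConfig()
        f1, f2, f3 = self.config.filters
        rng = np.random.default_rng(self.config.seed)
        cin = self.config.in_channels
        # periodic (circumferential) + edge-replicate (longitudinal) padding
        # throughout: pooling preserves the row periodicity, so every depth
        # of the network still sees a closed tube, and constant inputs map to
        # constant outputs (exact sliding-window stitching invariance)
        self.enc1 = _Block(cin, f1, "periodic", rng)
        self.enc2 = _Block(f1, f2, "periodic", rng)
        self.enc3 = _Block(f2, f3, "periodic", rng)
        self.dec1 = _Block(f3 + f2, f2, "periodic", rng)
        self.dec2 = _Block(f2 + f1, f1, "periodic", rng)
        self.dec3 = _Block(f1, f1, "periodic", rng)
        self.out_conv = Conv2d(f1, self.config.out_channels, k=1, pad_mode="zero", rng=rng)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[3] != self.config.in_channels:
            raise ValueError(
                f"expected (B, H, W, {self.config.in_channels}) input, got {x.shape}"
            )
        scale = np.ones(self.config.in_channels)
        scale[0:9] = self.config.coord_scale
        x = x * Tensor(scale)
        s1 = self.enc1(x)
        s2 = self.enc2(s1.maxpool2x())
        s3 = self.enc3(s2.maxpool2x())
        u1 = s3.resize_bilinear(s2.shape[1], s2.shape[2])
        d1 = self.dec1(Tensor.concat([u1, s2], axis=3))
        u2 = d1.resize_bilinear(s1.shape[1], s1.shape[2])
        d2 = self.dec2(Tensor.concat([u2, s1], axis=3))
        d3 = self.dec3(d2)
        return self.out_conv(d3)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> dict:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                state[f"bn_{j}_mean"] = m.running_mean
                state[f"bn_{j}_var"] = m.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"param_{i}"], dtype=float).reshape(p.data.shape)
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                m.running_mean = np.asarray(state[f"bn_{j}_mean"], dtype=float)
                m.running_var = np.asarray(state[f"bn_{j}_var"], dtype=float)


def periodic_pad(patch: np.ndarray, p: int) -> np.ndarray:
    """Reference periodic/replicate padding on a (H, W, C) array.

    Rows (circumferential) wrap; columns (longitudinal) replicate the edge.
    """
    t = Tensor(patch[None])
    return t.pad2d(p, row_mode="periodic", col_mode="replicate").data[0]


def predict_flatmap(model: WSSNet, flatmap: Flatmap, stride: int = 15) -> Flatmap:
    """Full-flatmap inference by sliding 48 x 48 windows along V.

    Overlapping window predictions are averaged; the output carries the input
    mask. Evaluation mode (running batch-norm statistics) is used.
    """
    nu, nv = flatmap.shape
    patch = model.config.patch
    if nu != patch:
        raise ValueError(f"flatmap circumference {nu} != patch edge {patch}")
    if nv < patch:
        raise ValueError(f"flatmap length {nv} < patch edge {patch}")
    model.eval()
    starts = list(range(0, nv - patch + 1, stride))
    if starts[-1] != nv - patch:
        starts.append(nv - patch)
    acc = np.zeros((nu, nv, model.config.out_channels))
    cnt = np.zeros((nu, nv, 1))
    from .train import center_coordinates

    batch = np.stack(
        [center_coordinates(flatmap.values[:, s : s + patch, :]) for s in starts], axis=0
    )
    pred = model(Tensor(batch)).data
    for b, s in enumerate(starts):
        acc[:, s : s + patch, :] += pred[b]
        cnt[:, s : s + patch, :] += 1.0
    return Flatmap(acc / cnt, flatmap.mask.copy(), ("wss_x", "wss_y", "wss_z"))
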