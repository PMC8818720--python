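"""Network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Module:
    """Base class: tracks parameters and train/eval mode."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False


class Conv2d(Module):
    """3x3 (or kxk) convolution with same-size output.

    ``pad_mode='periodic'`` wraps the circumferential axis and replicates the
    longitudinal edges (used before the first two convolutions); ``'zero'``
    zero-pads both axes (interior convolutions). Uniform fan-in init.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, pad_mode: str = "zero",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(cin * k * k)
        self.weight = Tensor(rng.uniform(-bound, bound, (k, k, cin, cout)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, (cout,)), requires_grad=True)
        self.k = k
        self.pad_mode = pad_mode
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        p = self.k // 2
        if p > 0:
            if self.pad_mode == "periodic":
                x = x.pad2d(p, row_mode="periodic", col_mode="replicate")
            else:
                x = x.pad2d(p, row_mode="zero", col_mode="zero")
        return x.conv2d_valid(self.weight, self.bias)


class BatchNorm(Module):
    """Per-channel batch normalization over (B, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True
        self.calibrating = False
        self._cal_n = 0.0
        self._cal_sum = np.zeros(channels)
        self._cal_sumsq = np.zeros(channels)

    def start_calibration(self) -> None:
        """Begin re-estimating inference statistics from exact global moments.

        The exponential running average under-counts the between-batch
        variance of the activations; a calibration sweep over deterministic
        batches accumulates true population moments instead.
        """
        self.calibrating = True
        self._cal_n = 0.0
        self._cal_sum[:] = 0.0
        self._cal_sumsq[:] = 0.0

    def finish_calibration(self) -> None:
        if self._cal_n > 0:
            mean = self._cal_sum / self._cal_n
            self.running_mean = mean
            self.running_var = np.maximum(self._cal_sumsq / self._cal_n - mean**2, 0.0)
        self.calibrating = False

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 1, 2), keepdims=True)
            if self.calibrating:
                n = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
                self._cal_n += n
                self._cal_sum += x.data.sum(axis=(0, 1, 2))
                self._cal_sumsq += (x.data**2).sum(axis=(0, 1, 2))
            else:
                self.running_mean = (
                    (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
                )
                self.running_var = (
                    (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
                )
            inv = (var + self.eps) ** -0.5
            xhat = centered * inv
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv
        return xhat * self.gamma + self.beta


class Adam:
    """Adam optimizer with externally scheduled learning rate."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_annealing_lr(epoch: int, cycle: int = 10, lr_max: float = 1e-4,
                        lr_min: float = 1e-7) -> float:
    """Cosine-annealed learning rate restarting every ``cycle`` epochs."""
    phase = (epoch % cycle) / cycle
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + np.cos(np.pi * phase))
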