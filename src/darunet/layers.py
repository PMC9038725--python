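"""Trainable layers used by the segmentation networks.

All layers consume and produce NHWC tensors. Convolution weights are
initialised from a zero-mean normal distribution (std 0.02 by default)
and biases start at zero. Batch normalisation keeps exponential running
statistics for inference, with trainable per-channel scale and shift.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d"]


class Module:
    """Base class: tracks parameters/submodules, train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
                isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for key, (holder, attr) in self._all_buffers().items():
            state[key] = getattr(holder, attr).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = self._all_buffers()
        for key, val in state.items():
            if key in own:
                if own[key].data.shape != val.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: "
                        f"{own[key].data.shape} vs {val.shape}")
                own[key].data = np.array(val, dtype=np.float64)
            elif key in bufs:
                holder, attr = bufs[key]
                object.__setattr__(holder, attr, np.array(val, dtype=np.float64))
            else:
                raise KeyError(f"unexpected key in state dict: {key}")
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def _all_buffers(self, prefix: str = "") -> dict:
        out = {}
        for key in self._buffers():
            out[prefix + key] = (self, key)
        for name, m in self._modules.items():
            out.update(m._all_buffers(prefix + name + "."))
        return out


class Conv2d(Module):
    """Same-padded 2-D convolution, weight (kh, kw, cin, cout)."""

    def __init__(self, cin: int, cout: int, kernel_size: int = 5,
                 stride: int = 1, init_std: float = 0.02, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.weight = Parameter(
            rng.normal(0.0, init_std, (kernel_size, kernel_size, cin, cout)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride)


class ConvTranspose2d(Module):
    """Same-padded transposed convolution; spatial dims scale by `stride`."""

    def __init__(self, cin: int, cout: int, kernel_size: int = 5,
                 stride: int = 2, init_std: float = 0.02,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.weight = Parameter(
            rng.normal(0.0, init_std, (kernel_size, kernel_size, cin, cout)))
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, stride=self.stride)


class BatchNorm2d(Module):
    """Per-channel batch normalisation over (N, H, W).

    Training mode normalises by batch statistics and updates running
    moments with momentum 0.99; inference uses the running statistics.
    """

    def __init__(self, channels: int, momentum: float = 0.99,
                 eps: float = 1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        object.__setattr__(self, "running_mean", np.zeros(channels))
        object.__setattr__(self, "running_var", np.ones(channels))

    def _buffers(self):
        return {"running_mean": self.running_mean,
                "running_var": self.running_var}

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 1, 2), keepdims=True)
            m = self.momentum
            object.__setattr__(
                self, "running_mean",
                m * self.running_mean + (1 - m) * mu.data.ravel())
            object.__setattr__(
                self, "running_var",
                m * self.running_var + (1 - m) * var.data.ravel())
            return self.gamma * ((x - mu) / ((var + self.eps).sqrt())) + self.beta
        scale = self.gamma * (1.0 / np.sqrt(self.running_var + self.eps))
        return scale * (x - Tensor(self.running_mean)) + self.beta
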