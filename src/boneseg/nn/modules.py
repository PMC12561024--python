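"""Layer modules: parameter containers over the fused functional ops."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autodiff import Tensor


def _kaiming_uniform(rng, shape, fan_in, dtype=np.float32):
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(dtype),
                  requires_grad=True)


class Module:
    """Base class with recursive parameter/buffer discovery by attribute name."""

    def __init__(self):
        self.training = True

    def modules(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, mod in self.modules():
            yield from mod.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, mod in self.modules():
            yield from mod.named_buffers(prefix=f"{prefix}{name}.")

    def train(self, mode=True):
        self.training = mode
        for _, mod in self.modules():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self):
        return sum(int(p.data.size) for p in self.parameters())

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        own_p = dict(self.named_parameters())
        own_b = dict(self.named_buffers())
        missing = (set(own_p) | set(own_b)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")
        for name, p in own_p.items():
            p.data = np.array(state[name], dtype=p.data.dtype)
        for name, b in own_b.items():
            b[...] = state[name]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, rng,
                 stride=1, padding=1):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = _kaiming_uniform(
            rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        self.bias = _kaiming_uniform(rng, (out_channels,), fan_in)

    def __call__(self, x):
        return F.conv2d(x, self.weight, self.bias,
                        stride=self.stride, pad=self.padding)


class DWConv3x3(Module):
    def __init__(self, channels, rng):
        super().__init__()
        self.weight = _kaiming_uniform(rng, (channels, 3, 3), 9)
        self.bias = _kaiming_uniform(rng, (channels,), 9)

    def __call__(self, x):
        return F.dwconv3x3(x, self.weight, self.bias)


class Linear(Module):
    """Token 'fc' layer: per-pixel linear map over channels."""

    def __init__(self, in_features, out_features, rng):
        super().__init__()
        self.weight = _kaiming_uniform(rng, (out_features, in_features), in_features)
        self.bias = _kaiming_uniform(rng, (out_features,), in_features)

    def __call__(self, x):
        return F.linear_channels(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffer_names = ("running_mean", "running_var")

    def __call__(self, x):
        return F.batchnorm2d(x, self.gamma, self.beta,
                             self.running_mean, self.running_var,
                             self.training, self.momentum, self.eps)


class LayerNormChannels(Module):
    def __init__(self, channels, eps=1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return F.layernorm_channels(x, self.gamma, self.beta, self.eps)
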