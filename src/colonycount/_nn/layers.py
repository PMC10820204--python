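"""Layer/module abstractions on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    add,
    conv2d,
    matmul,
    relu,
)

__all__ = ["Parameter", "Module", "Conv2d", "BatchNorm2d", "Linear", "ConvBnRelu"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self):
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    yield v

    def named_state(self):
        """Flat {name: array} of parameters and buffers, in stable order."""
        state = {}

        def visit(mod, prefix):
            idx = 0
            for k, v in mod.__dict__.items():
                if isinstance(v, Parameter):
                    state[f"{prefix}{k}"] = v.data
                elif isinstance(v, np.ndarray) and k.startswith("running_"):
                    state[f"{prefix}{k}"] = v
                elif isinstance(v, Module):
                    visit(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{k}.{i}.")
                idx += 1

        visit(self, "")
        return state

    def load_state(self, state):
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)[:5]}")
        for name in own:
            own[name][...] = state[name]

    def copy_state(self):
        return {k: v.copy() for k, v in self.named_state().items()}

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self):
        return sum(p.data.size for p in self.parameters())


def _he_normal(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, c_in, c_out, k=3, *, stride=1, padding=None, dilation=1,
                 bias=True, rng=None):
        super().__init__()
        if padding is None:
            padding = dilation * (k - 1) // 2  # 'same' for odd k, stride 1
        self.stride, self.padding, self.dilation = stride, padding, dilation
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_normal(rng, (c_out, c_in, k, k), c_in * k * k))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x.data - mu[None, :, None, None]) / std[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        gamma, beta, training = self.gamma, self.beta, self.training
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if x.requires_grad:
                gs = gamma.data[None, :, None, None] / std[None, :, None, None]
                if training:
                    gm = g.mean(axis=axes)[None, :, None, None]
                    gxm = (g * xhat).mean(axis=axes)[None, :, None, None]
                    dx = gs * (g - gm - xhat * gxm)
                else:
                    dx = gs * g
                x._accum(dx.astype(np.float32))

        return Tensor(out, parents=(x, gamma, beta), backward=backward)


class Linear(Module):
    def __init__(self, f_in, f_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_he_normal(rng, (f_in, f_out), f_in))
        self.bias = Parameter(np.zeros(f_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class ConvBnRelu(Module):
    """conv -> batch norm -> ReLU, the basic unit of both networks."""

    def __init__(self, c_in, c_out, *, dilation=1, stride=1, rng=None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, 3, stride=stride, dilation=dilation,
                           bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))
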