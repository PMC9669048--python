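"""Layer/module containers over the autodiff primitives."""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Tensor


class Module:
    """Base container: recursive parameter/buffer discovery, train/eval mode."""

    def __init__(self):
        self._training = True

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self._training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    @property
    def training(self) -> bool:
        return self._training

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.named_parameters():
            v.data = state[f"param.{k}"].copy()
        for k, v in self.named_buffers():
            v[...] = state[f"buffer.{k}"]


class Conv1d(Module):
    """Dense 1-D convolution with He-normal init; pointwise when k=1."""

    def __init__(self, cin, cout, k=1, stride=1, dilation=1, bias=True, *, rng, dtype):
        super().__init__()
        self.stride, self.dilation = stride, dilation
        std = np.sqrt(2.0 / (cin * k))
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, k)).astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv1d(x, self.weight, self.bias, self.stride, self.dilation)


class DepthwiseConv1d(Module):
    def __init__(self, ch, k=3, stride=1, dilation=1, *, rng, dtype):
        super().__init__()
        self.stride, self.dilation = stride, dilation
        std = np.sqrt(2.0 / k)
        self.weight = Tensor(rng.normal(0.0, std, (ch, k)).astype(dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return F.depthwise_conv1d(x, self.weight, self.stride, self.dilation)


class SeparableConv1d(Module):
    """Depthwise spatial convolution followed by a pointwise projection."""

    def __init__(self, cin, cout, k=3, stride=1, dilation=1, *, rng, dtype):
        super().__init__()
        self.depthwise = DepthwiseConv1d(cin, k, stride, dilation, rng=rng, dtype=dtype)
        self.pointwise = Conv1d(cin, cout, 1, rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class BatchNorm1d(Module):
    def __init__(self, ch, momentum=0.1, eps=1e-5, *, dtype):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(ch, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=np.float64)
        self.running_var = np.ones(ch, dtype=np.float64)

    def __call__(self, x: Tensor) -> Tensor:
        return F.batchnorm1d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class ConvBnElu(Module):
    """conv -> batch norm -> ELU, the unit every encoder/decoder layer uses."""

    def __init__(self, conv: Module, ch: int, *, dtype):
        super().__init__()
        self.conv = conv
        self.bn = BatchNorm1d(ch, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return F.elu(self.bn(self.conv(x)))


class Adam(Module):
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        super().__init__()
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        b1, b2 = self.betas
        self.t += 1
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= (self.lr / corr1) * m / (np.sqrt(v / corr2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
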