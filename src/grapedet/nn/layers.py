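"""Layer/module abstractions over the autodiff tensors."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "BatchNorm2d", "ConvBlock", "Sequential", "Identity"]


class Parameter(Tensor):
    """Learnable tensor (``requires_grad=True`` by default)."""

    def __init__(self, data, requires_grad: bool = True):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=requires_grad)


class Module:
    """Composable network block with recursive parameter discovery."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- serialization ----------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value._named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{full}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: buf.copy() for name, buf in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, array in state.items():
            if name in params:
                if params[name].shape != array.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = array.astype(np.float32).copy()
            elif name in buffers:
                buffers[name][...] = array
            else:
                raise KeyError(f"unexpected state entry {name}")

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init
        self.weight = Parameter(rng.normal(0.0, scale, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = kernel // 2

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mean
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mean.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
            xhat = centred * ((var + self.eps) ** -0.5)
        else:
            mean = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - mean) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


_ACTS = {
    "mish": T.mish,
    "leaky": lambda x: T.leaky_relu(x, 0.1),
    "linear": lambda x: x,
}


class ConvBlock(Module):
    """Conv + BatchNorm + activation.

    ``act='mish'`` gives the backbone's CBM block, ``act='leaky'`` the
    neck/head CBL block, ``act='linear'`` a bare projection.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 act: str = "mish", rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride=stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)
        self.act_name = act
        self._act = _ACTS[act]

    def forward(self, x: Tensor) -> Tensor:
        return self._act(self.bn(self.conv(x)))


class Sequential(Module):
    def __init__(self, *blocks: Module):
        super().__init__()
        self.blocks = list(blocks)

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
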