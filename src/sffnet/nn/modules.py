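"""Layer modules with named parameters and checkpoint (de)serialization."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "ModuleList"]


class Module:
    """Base class: tracks sub-modules/parameters by attribute name."""

    def __init__(self):
        self.training = True

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield from m.named_parameters(f"{key}.{i}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Module):
                yield from val.named_buffers(f"{key}.")
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield from m.named_buffers(f"{key}.{i}.")
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                yield key, val

    def modules(self) -> Iterator["Module"]:
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, ModuleList):
                for m in val:
                    yield from m.modules()

    # -- mode -------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- checkpointing ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: buf.copy() for name, buf in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_params = dict(self.named_parameters())
        own_bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in own_params:
                if own_params[name].data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{own_params[name].data.shape} vs {arr.shape}"
                    )
                own_params[name].data[...] = arr
            elif name in own_bufs:
                own_bufs[name][...] = arr
            else:
                raise KeyError(f"unknown tensor in state dict: {name}")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    """A plain list that module traversal descends into."""


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """He initialization with fan_out, appropriate before ReLU."""
    if len(shape) == 4:
        fan_out = shape[0] * shape[2] * shape[3]
    else:
        fan_out = shape[0]
    std = np.sqrt(2.0 / fan_out)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stride = stride
        self.pad = pad
        self.weight = Parameter(kaiming_normal(rng, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, num_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(num_ch, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_ch, dtype=np.float32))
        self.running_mean = np.zeros(num_ch, dtype=np.float32)
        self.running_var = np.ones(num_ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(
            x,
            self.weight,
            self.bias,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(out_features, in_features)).astype(np.float32)
        )
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        out = x.data @ w.data.T + b.data

        def bw(g: np.ndarray) -> None:
            if w.requires_grad:
                w._accumulate(g.T @ x.data)
            if b.requires_grad:
                b._accumulate(g.sum(axis=0))
            if x.requires_grad:
                x._accumulate(g @ w.data)

        return Tensor(out, parents=(x, w, b), backward=bw)
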