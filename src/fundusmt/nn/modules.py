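"""Layer modules for the fundus networks.

Conventions: convolutions are 3x3 (padding 1) or 1x1; a "conv block" is
conv -> batch-norm -> LeakyReLU(0.1); convolutions followed by batch norm
carry no bias.  Weight init is Kaiming fan-in normal driven by an explicit
``numpy.random.Generator`` so every build is reproducible from a seed.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

import numpy as np

from . import autodiff as F
from .autodiff import Tensor

LEAKY_SLOPE = 0.1


class Parameter(Tensor):
    def __init__(self, data: np.ndarray, name: str = "") -> None:
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True, name=name)


def kaiming_conv(rng: np.random.Generator, cout: int, cin: int, k: int) -> np.ndarray:
    fan_in = cin * k * k
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=(cout, cin, k, k))


class Module:
    """Minimal module container: tracks sub-modules and parameters by name."""

    def __init__(self) -> None:
        self._training = True

    # -- parameter traversal -------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for key, val in vars(self).items():
            if key.startswith("_"):
                continue
            name = f"{prefix}{key}" if prefix else key
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for key, val in vars(self).items():
            if key.startswith("_"):
                continue
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- training mode -------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m._training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    @property
    def training(self) -> bool:
        return self._training

    # -- state ---------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, mod in self._named_bn():
            state[f"{name}.running_mean"] = mod.running_mean.copy()
            state[f"{name}.running_var"] = mod.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"missing parameter in state dict: {name}")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.array(state[name], dtype=np.float32, copy=True)
        for name, mod in self._named_bn():
            if f"{name}.running_mean" in state:
                mod.running_mean[...] = state[f"{name}.running_mean"]
                mod.running_var[...] = state[f"{name}.running_var"]

    def _named_bn(self, prefix: str = "") -> Iterator[tuple[str, "BatchNorm2d"]]:
        for key, val in vars(self).items():
            if key.startswith("_"):
                continue
            name = f"{prefix}{key}" if prefix else key
            if isinstance(val, BatchNorm2d):
                yield name, val
            elif isinstance(val, Module):
                yield from val._named_bn(name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item._named_bn(f"{name}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, rng: np.random.Generator, cin: int, cout: int, k: int = 3,
                 stride: int = 1, dilation: int = 1, bias: bool = True) -> None:
        super().__init__()
        self.weight = Parameter(kaiming_conv(rng, cout, cin, k))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self._stride = stride
        self._dilation = dilation
        self._padding = dilation * (k - 1) // 2

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self._stride,
                        padding=self._padding, dilation=self._dilation)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self._momentum = momentum
        self._eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batchnorm2d(x, self.weight, self.bias,
                             running_mean=self.running_mean,
                             running_var=self.running_var,
                             training=self._training,
                             momentum=self._momentum, eps=self._eps)


class ConvBlock(Module):
    """conv -> BN -> LeakyReLU.  Stride 2 halves even spatial sizes exactly."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int,
                 k: int = 3, stride: int = 1, dilation: int = 1) -> None:
        super().__init__()
        if stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {stride}")
        self.conv = Conv2d(rng, cin, cout, k=k, stride=stride, dilation=dilation, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return F.leaky_relu(self.bn(self.conv(x)), LEAKY_SLOPE)


class Bottleneck(Module):
    """Residual 1x1 -> 3x3 unit with an additive identity skip."""

    def __init__(self, rng: np.random.Generator, c: int) -> None:
        super().__init__()
        self.cv1 = ConvBlock(rng, c, c, k=1)
        self.cv2 = ConvBlock(rng, c, c, k=3)

    def forward(self, x: Tensor) -> Tensor:
        return F.add(x, self.cv2(self.cv1(x)))


class BottleneckCSP(Module):
    """Cross-stage-partial block.

    The input is split into two half-width paths: one runs a chain of
    residual bottlenecks (feature summation), the other is a plain 1x1
    projection (channel shortcut).  The paths are concatenated, normalised,
    and fused back to ``cout`` channels.
    """

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, repeats: int = 1) -> None:
        super().__init__()
        if cout % 2:
            raise ValueError(f"BottleneckCSP needs even out channels, got {cout}")
        h = cout // 2
        self.cv1 = ConvBlock(rng, cin, h, k=1)
        self.blocks = [Bottleneck(rng, h) for _ in range(repeats)]
        self.cv2 = Conv2d(rng, cin, h, k=1, bias=True)  # shortcut path, raw conv
        self.bn = BatchNorm2d(2 * h)
        self.cv4 = ConvBlock(rng, 2 * h, cout, k=1)

    def forward(self, x: Tensor) -> Tensor:
        a = self.cv1(x)
        for blk in self.blocks:
            a = blk(a)
        b = self.cv2(x)
        y = F.leaky_relu(self.bn(F.concat_channels([a, b])), LEAKY_SLOPE)
        return self.cv4(y)


class ASPP(Module):
    """Atrous spatial pyramid pooling: a 1x1 branch plus one 3x3 dilated
    branch per rate (default 6/12/18), concatenated and 1x1-projected."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int,
                 branch: int, rates: Sequence[int] = (6, 12, 18)) -> None:
        super().__init__()
        rates = tuple(rates)
        if any(r <= 0 for r in rates):
            raise ValueError(f"ASPP rates must be positive, got {rates}")
        if list(rates) != sorted(set(rates)) and len(set(rates)) > 1:
            raise ValueError(f"ASPP rates must be strictly increasing, got {rates}")
        self.branch1 = ConvBlock(rng, cin, branch, k=1)
        self.branches = [ConvBlock(rng, cin, branch, k=3, dilation=r) for r in rates]
        self.project = ConvBlock(rng, (1 + len(rates)) * branch, cout, k=1)

    def forward(self, x: Tensor) -> Tensor:
        outs = [self.branch1(x)] + [b(x) for b in self.branches]
        return self.project(F.concat_channels(outs))


class UpsampleBlock(Module):
    """Bilinear x2 upsampling followed by a conv block."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int) -> None:
        super().__init__()
        self.conv = ConvBlock(rng, cin, cout, k=3)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(F.upsample_bilinear2x(x))


class Linear(Module):
    def __init__(self, rng: np.random.Generator, nin: int, nout: int) -> None:
        super().__init__()
        std = np.sqrt(2.0 / nin)
        self.weight = Parameter(rng.normal(0.0, std, size=(nout, nin)))
        self.bias = Parameter(np.zeros(nout))

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)
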