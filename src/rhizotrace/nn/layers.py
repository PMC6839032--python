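"""Layer modules over the autodiff engine.

Thin, stateful wrappers (parameters + running statistics) around the
functional primitives in :mod:`rhizotrace.nn.autodiff`.  Initialization is
He-normal from a caller-supplied generator so that model construction is
fully deterministic.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2x",
    "BatchNorm2d",
    "Residual",
    "Hourglass",
]


class Module:
    """Minimal module: named parameters, submodules, train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        super().__setattr__(name, value)

    def register(self, name: str, tensor: Tensor) -> Tensor:
        tensor.requires_grad = True
        self._params[name] = tensor
        setattr(self, name, tensor)
        return tensor

    def parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for name, mod in self._modules.items():
            out.extend(mod.parameters(prefix + name + "."))
        return out

    def buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = []
        for name in getattr(self, "_buffers", ()):  # set by BatchNorm2d
            out.append((prefix + name, getattr(self, name)))
        for name, mod in self._modules.items():
            out.extend(mod.buffers(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for _, p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for _, p in self.parameters()))


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=0, bias=True, *, rng):
        super().__init__()
        std = np.sqrt(2.0 / (cin * k * k))
        self.register(
            "weight", Tensor(rng.normal(0, std, size=(cout, cin, k, k)))
        )
        self.has_bias = bias
        if bias:
            self.register("b", Tensor(np.zeros(cout)))
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        bias = self.b if self.has_bias else None
        return ad.conv2d(x, self.weight, bias, stride=self.stride, pad=self.pad)


class ConvTranspose2x(Module):
    """Kernel 2x2, stride 2 transposed convolution (spatial doubling)."""

    def __init__(self, cin, cout, bias=False, *, rng):
        super().__init__()
        std = np.sqrt(2.0 / (cin * 4))
        self.register("weight", Tensor(rng.normal(0, std, size=(cin, cout, 2, 2))))
        self.has_bias = bias
        if bias:
            self.register("b", Tensor(np.zeros(cout)))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d_2x(
            x, self.weight, getattr(self, "b", None) if self.has_bias else None
        )


class BatchNorm2d(Module):
    def __init__(self, c):
        super().__init__()
        self.register("gamma", Tensor(np.ones(c)))
        self.register("beta", Tensor(np.zeros(c)))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")

    def __call__(self, x: Tensor) -> Tensor:
        return ad.batch_norm(
            x, self.gamma, self.beta,
            self.running_mean, self.running_var, self.training,
        )


class Residual(Module):
    """Pre-activation bottleneck residual block.

    BN-ReLU-1x1 (reduce to out/4) -> BN-ReLU-3x3 -> BN-ReLU-1x1 (expand to
    out); identity skip, with a 1x1 projection only when the channel count
    changes.  Convolutions carry no bias (each is preceded or followed by a
    normalization).  The expansion convolution is initialized at a quarter
    of the He scale so each block starts close to the identity — the
    pre-activation analogue of zero-initializing the last normalization
    layer of a residual block, which speeds up early training.
    """

    def __init__(self, cin, cout, *, rng):
        super().__init__()
        mid = max(cout // 4, 1)
        self.bn1 = BatchNorm2d(cin)
        self.conv1 = Conv2d(cin, mid, 1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, mid, 3, pad=1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(mid)
        self.conv3 = Conv2d(mid, cout, 1, bias=False, rng=rng)
        self.conv3.weight.data *= 0.25
        self.proj = Conv2d(cin, cout, 1, bias=False, rng=rng) if cin != cout else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv1(ad.relu(self.bn1(x)))
        y = self.conv2(ad.relu(self.bn2(y)))
        y = self.conv3(ad.relu(self.bn3(y)))
        skip = self.proj(x) if self.proj is not None else x
        return ad.add(y, skip)


class Hourglass(Module):
    """Single (non-stacked) hourglass: recursive pool / residual / upsample.

    ``depth`` pooling levels; max pooling on the way down, bilinear
    upsampling on the way up, one residual block per slot, skip residual at
    every level.
    """

    def __init__(self, features, depth, *, rng):
        super().__init__()
        self.depth = depth
        self.up1 = Residual(features, features, rng=rng)
        self.low1 = Residual(features, features, rng=rng)
        if depth > 1:
            self.low2 = Hourglass(features, depth - 1, rng=rng)
        else:
            self.low2 = Residual(features, features, rng=rng)
        self.low3 = Residual(features, features, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        up = self.up1(x)
        low = self.low3(self.low2(self.low1(ad.maxpool2x2(x))))
        return ad.add(up, ad.upsample_bilinear2x(low))
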