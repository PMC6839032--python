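"""The multi-task segmentation/localization network.

An extended encoder-decoder: a strided 7x7 stem and two residual+pool
stages reduce a (3, S, S) input to S/8 resolution, a single depth-4
hourglass performs the main encoding/decoding, and two transposed
convolutions interleaved with residual blocks return to S/2 — half the
input side — where the trunk splits into two 1x1-convolution heads, one
emitting 3 segmentation channels (background, first-order, second-order)
and one emitting 3 feature heat-map channels (seed, first-order tips,
second-order tips).

The network is fully convolutional, so the trainable-parameter count is
independent of input size: 1,595,782 at width multiplier 1.  All feature
counts scale with ``width_multiplier`` for reduced test variants.

The segmentation head is dual-natured: its per-channel sigmoid feeds the
binary cross-entropy loss during training, while a softmax across the 3
channels yields normalized class maps at inference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import BatchNorm2d, Conv2d, ConvTranspose2x, Hourglass, Module, Residual

__all__ = ["NetworkSpec", "RootNet", "build_network", "count_parameters",
           "save_checkpoint", "load_checkpoint", "REFERENCE_PARAMETER_COUNT"]

#: trainable parameters of the width-1 network
REFERENCE_PARAMETER_COUNT = 1_595_782


@dataclass
class NetworkSpec:
    """Structural description of the network.

    ``width_multiplier`` scales every feature count (1 -> the reference
    architecture); input spatial size must be a multiple of 128 so the
    hourglass bottom level is well defined.
    """

    input_channels: int = 3
    n_classes: int = 3
    n_heatmaps: int = 3
    width_multiplier: float = 1.0
    hourglass_depth: int = 4
    init_seed: int = 0

    def validate(self) -> None:
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if self.hourglass_depth < 1:
            raise ValueError("hourglass_depth must be >= 1")

    def channels(self, base: int) -> int:
        return max(int(round(base * self.width_multiplier)), 4)


class RootNet(Module):
    """Encoder -> hourglass -> decoder trunk with twin 1x1 heads."""

    def __init__(self, spec: NetworkSpec):
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([spec.init_seed, 0x90071]))
        c64, c128, c256 = spec.channels(64), spec.channels(128), spec.channels(256)

        # stem: 7x7 stride-2 convolution to S/2
        self.stem = Conv2d(spec.input_channels, c64, 7, stride=2, pad=3,
                           bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(c64)
        # encoder: residual blocks interleaved with 2x2 max pooling to S/8
        self.res1 = Residual(c64, c128, rng=rng)
        self.res2 = Residual(c128, c256, rng=rng)
        self.res3 = Residual(c256, c256, rng=rng)
        # core: single hourglass at S/8
        self.hourglass = Hourglass(c256, spec.hourglass_depth, rng=rng)
        # decoder: transposed convolutions + residual blocks back to S/2
        self.up1 = ConvTranspose2x(c256, c256, rng=rng)
        self.res4 = Residual(c256, c256, rng=rng)
        self.up2 = ConvTranspose2x(c256, c128, rng=rng)
        self.res5 = Residual(c128, c64, rng=rng)
        self.neck = Conv2d(c64, c64, 1, bias=False, rng=rng)
        self.neck_bn = BatchNorm2d(c64)
        # heads
        self.seg_head = Conv2d(c64, spec.n_classes, 1, bias=True, rng=rng)
        self.heat_head = Conv2d(c64, spec.n_heatmaps, 1, bias=True, rng=rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Forward pass; returns (segmentation logits, heat maps) at S/2."""
        h = ad.relu(self.stem_bn(self.stem(x)))
        h = ad.maxpool2x2(self.res1(h))
        h = ad.maxpool2x2(self.res2(h))
        h = self.res3(h)
        h = self.hourglass(h)
        h = self.res4(self.up1(h))
        h = self.res5(self.up2(h))
        h = ad.relu(self.neck_bn(self.neck(h)))
        return self.seg_head(h), self.heat_head(h)

    # ------------------------------------------------------------------
    # inference conveniences (plain numpy in / numpy out)

    def predict(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode forward pass on a (B, 3, H, W) array.

        Returns softmax-normalized class probabilities and heat maps
        clipped to [0, 1], both (B, 3, H/2, W/2).
        """
        was_training = self.training
        self.eval()
        try:
            seg_logits, heat = self(Tensor(images))
        finally:
            self.train(was_training)
        z = seg_logits.data - seg_logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        seg = e / e.sum(axis=1, keepdims=True)
        return seg, np.clip(heat.data, 0.0, 1.0)


def build_network(spec: NetworkSpec | None = None) -> RootNet:
    """Construct the network from a spec (deterministic for a fixed init_seed)."""
    return RootNet(spec or NetworkSpec())


def count_parameters(model: Module) -> int:
    """Number of independently trainable scalar weights, including
    normalization affine terms."""
    return model.n_parameters()


def save_checkpoint(model: RootNet, path: str | Path) -> None:
    """Single-file checkpoint: weights + running stats + embedded spec."""
    arrays = {f"param:{k}": p.data for k, p in model.parameters()}
    arrays.update({f"buffer:{k}": b for k, b in model.buffers()})
    arrays["spec"] = np.frombuffer(
        json.dumps(asdict(model.spec)).encode(), dtype=np.uint8
    )
    np.savez(str(path), **arrays)


def load_checkpoint(path: str | Path, spec: NetworkSpec | None = None) -> RootNet:
    """Rebuild a model from a checkpoint.

    A mismatch between the stored arrays and the (possibly overridden)
    spec's layer shapes raises a ``ValueError`` naming the offending layer.
    """
    with np.load(str(path)) as data:
        stored = NetworkSpec(**json.loads(bytes(data["spec"]).decode()))
        model = build_network(spec or stored)
        for k, p in model.parameters():
            arr = data[f"param:{k}"]
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint layer {k}: stored shape {arr.shape} does not "
                    f"match model shape {p.data.shape}"
                )
            p.data = arr.astype(np.float32)
        for k, b in model.buffers():
            b[...] = data[f"buffer:{k}"]
    return model
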