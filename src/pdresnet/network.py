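"""The PD-ResNet architecture.

A 1x1 convolution stem maps the single-channel gait image to a first
feature bank, three residual layers (each two residual units, the first
strided) perform three downsamplings — 112 -> 56 -> 28 -> 14 for the
default input — adaptive global average pooling collapses the final
feature maps to a 512-value descriptor, and a 2-neuron linear head with
sigmoid activation emits per-class scores. A positive-class score of at
least 0.5 is read as the positive label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, GlobalAvgPool, Linear, Parameter, ReLU,
                 ResidualUnit, Sigmoid)

__all__ = [
    "ResidualUnitSpec",
    "NetworkSpec",
    "PDResNet",
    "build_network",
    "classify",
    "parameter_count",
]


@dataclass(frozen=True)
class ResidualUnitSpec:
    """Shape contract of one residual unit."""
    in_channels: int
    out_channels: int
    stride: int = 1
    kernel: int = 3

    @property
    def shortcut(self) -> str:
        needs_projection = self.stride != 1 or self.in_channels != self.out_channels
        return "projection" if needs_projection else "identity"


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    ``layer_channels`` lists the output channels of each residual layer;
    every layer starts with a stride-2 unit, so three layers give the three
    downsamplings of the reference design. The pooled descriptor dimension
    equals the last layer's channel count.
    """
    input_side: int = 112
    input_channels: int = 1
    stem_channels: int = 64
    layer_channels: tuple[int, ...] = (128, 256, 512)
    units_per_layer: int = 2
    n_outputs: int = 2

    def validate(self) -> None:
        if self.input_side < 8:
            raise ValueError(f"input_side must be >= 8, got {self.input_side}")
        if self.stem_channels < 1 or self.input_channels < 1:
            raise ValueError("channel counts must be positive")
        if len(self.layer_channels) < 1 or any(c < 1 for c in self.layer_channels):
            raise ValueError("layer_channels must be a non-empty tuple of positives")
        if self.units_per_layer < 1:
            raise ValueError("units_per_layer must be >= 1")
        if self.n_outputs != 2:
            raise ValueError("the binary head has exactly 2 output neurons")

    @property
    def descriptor_dim(self) -> int:
        return self.layer_channels[-1]

    @classmethod
    def default(cls) -> "NetworkSpec":
        return cls()

    @classmethod
    def compact(cls, input_side: int = 20) -> "NetworkSpec":
        """Desk-scale preset: same topology, narrow channel plan."""
        return cls(input_side=input_side, stem_channels=8,
                   layer_channels=(16, 32, 64))


class PDResNet:
    """The residual gait classifier, with explicit forward and backward.

    Parameters are initialized deterministically from ``seed`` (Kaiming
    fan-in normal for convolutions and the head, unit/zero for batch
    norm). ``forward`` records the spatial side after each residual layer
    in ``spatial_sides`` so downsampling can be probed.
    """

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0,
                 dtype=np.float32):
        self.spec = spec or NetworkSpec()
        self.spec.validate()
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        s = self.spec
        self.stem_conv = Conv2d(s.input_channels, s.stem_channels, 1,
                                rng=rng, dtype=dtype)
        self.stem_bn = BatchNorm2d(s.stem_channels, dtype=dtype)
        self.stem_relu = ReLU()
        self.layers: list[list[ResidualUnit]] = []
        in_ch = s.stem_channels
        for ch in s.layer_channels:
            units = [ResidualUnit(in_ch, ch, stride=2, rng=rng, dtype=dtype)]
            for _ in range(s.units_per_layer - 1):
                units.append(ResidualUnit(ch, ch, stride=1, rng=rng, dtype=dtype))
            self.layers.append(units)
            in_ch = ch
        self.pool = GlobalAvgPool()
        self.head = Linear(in_ch, s.n_outputs, rng=rng, dtype=dtype)
        self.sigmoid = Sigmoid()
        self.spatial_sides: list[int] = []

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Batch of images (N, 1, side, side) -> per-sample (N, 2) scores in [0, 1]."""
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[:, None]
        s = self.spec
        if x.ndim != 4 or x.shape[1] != s.input_channels \
                or x.shape[2] != s.input_side or x.shape[3] != s.input_side:
            raise ValueError(
                f"expected input of shape (N, {s.input_channels}, "
                f"{s.input_side}, {s.input_side}), got {x.shape}")
        h = np.ascontiguousarray(x, dtype=self.dtype)
        h = self.stem_relu.forward(self.stem_bn.forward(
            self.stem_conv.forward(h, train), train), train)
        self.spatial_sides = []
        for units in self.layers:
            for unit in units:
                h = unit.forward(h, train)
            self.spatial_sides.append(h.shape[-1])
        d = self.pool.forward(h, train)
        z = self.head.forward(d, train)
        return self.sigmoid.forward(z, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(scores); returns d(loss)/d(input)."""
        d = self.sigmoid.backward(np.asarray(dout, dtype=self.dtype))
        d = self.head.backward(d)
        d = self.pool.backward(d)
        for units in reversed(self.layers):
            for unit in reversed(units):
                d = unit.backward(d)
        d = self.stem_relu.backward(d)
        d = self.stem_bn.backward(d)
        return self.stem_conv.backward(d)

    # -- bookkeeping --------------------------------------------------------

    def _modules(self):
        mods = [self.stem_conv, self.stem_bn]
        for units in self.layers:
            mods.extend(units)
        mods.append(self.head)
        return mods

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for mod in self._modules():
            params.extend(mod.parameters())
        return params

    def buffers(self) -> list[np.ndarray]:
        bufs: list[np.ndarray] = []
        for mod in self._modules():
            bufs.extend(mod.buffers())
        return bufs

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, list[np.ndarray]]:
        return {"params": [p.data.copy() for p in self.parameters()],
                "buffers": [b.copy() for b in self.buffers()]}

    def load_state_dict(self, state: dict[str, list[np.ndarray]]) -> None:
        for p, saved in zip(self.parameters(), state["params"], strict=True):
            p.data[...] = saved
        for b, saved in zip(self.buffers(), state["buffers"], strict=True):
            b[...] = saved

    def zero_residual_branches(self) -> None:
        """Diagnostic: make every residual unit compute activation(shortcut(x))."""
        for units in self.layers:
            for unit in units:
                unit.zero_branch()

    @property
    def descriptor_dim(self) -> int:
        return self.spec.descriptor_dim


def build_network(spec: NetworkSpec | None = None, seed: int = 0,
                  dtype=np.float32) -> PDResNet:
    return PDResNet(spec, seed=seed, dtype=dtype)


def parameter_count(spec: NetworkSpec) -> int:
    """Total trainable parameter count implied by a spec."""
    return PDResNet(spec, seed=0).num_parameters()


def classify(probabilities, threshold: float = 0.5):
    """Map positive-class score(s) to labels; score >= threshold is positive."""
    p = np.asarray(probabilities, dtype=float)
    labels = (p >= threshold).astype(int)
    return int(labels) if p.ndim == 0 else labels
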