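"""Building blocks: BN-ReLU-Conv units, dense/transition/prediction blocks,
and the three 1D squeeze-and-excitation variants (cSE, sSE, scSE).

Dense blocks follow the densely-connected pattern: layer ``l`` consumes the
concatenation of the block input and every previous layer's output, and the
block emits the concatenation of its input with all layer outputs.  Transition
blocks compress channels by a factor ``c`` with a kernel-1 convolution and
halve the length with average pooling.  SE blocks recalibrate a feature map:
cSE squeezes spatially (global average pool per channel,
``z_k = mean_i u_k(i)``) and excites channel-wise through a two-layer
bottleneck gate; sSE squeezes channels with a kernel-1 convolution and excites
per position; scSE combines both.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for convenience)
    BatchNorm1d,
    Conv1d,
    Linear,
    Module,
    Tensor,
    avg_pool1d,
    concat,
    global_avg_pool,
    maximum,
)

__all__ = [
    "ConvBlock",
    "DenseBlock",
    "TransitionBlock",
    "PredictionBlock",
    "ChannelSE",
    "SpatialSE",
    "ConcurrentSE",
    "make_se_block",
    "se_bottleneck_width",
]


class ConvBlock(Module):
    """Composite BN -> ReLU -> Conv(kernel 3, same padding)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel_size: int = 3):
        super().__init__()
        self.bn = BatchNorm1d(in_channels)
        self.conv = Conv1d(in_channels, out_channels, kernel_size, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(self.bn(x).relu())


class DenseBlock(Module):
    """``n_convs`` conv blocks with dense (concatenative) connectivity.

    Output channels = input channels + n_convs * growth_rate; length unchanged.
    """

    def __init__(self, in_channels: int, growth_rate: int, n_convs: int,
                 rng: np.random.Generator):
        super().__init__()
        self.layers = [
            ConvBlock(in_channels + i * growth_rate, growth_rate, rng)
            for i in range(n_convs)
        ]
        self.out_channels = in_channels + n_convs * growth_rate

    def forward(self, x: Tensor) -> Tensor:
        features = [x]
        for layer in self.layers:
            inp = features[0] if len(features) == 1 else concat(features, axis=1)
            features.append(layer(inp))
        return features[0] if len(features) == 1 else concat(features, axis=1)


class TransitionBlock(Module):
    """BN -> ReLU -> Conv(kernel 1) to floor(c * C) channels -> AvgPool(2).

    Compresses channels and halves the length between dense blocks.
    """

    def __init__(self, in_channels: int, compression: float, rng: np.random.Generator):
        super().__init__()
        self.out_channels = max(1, int(np.floor(compression * in_channels)))
        self.bn = BatchNorm1d(in_channels)
        self.conv = Conv1d(in_channels, self.out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return avg_pool1d(self.conv(self.bn(x).relu()), size=2)


class PredictionBlock(Module):
    """Global average pool -> fully connected -> ReLU -> fixed output gain.

    The fully connected layer regresses fractional landmark positions inside
    the padded window; the fixed gain (window length, 250) converts them to
    sample-index units.  ReLU (not softmax) keeps positions nonnegative and
    unbounded above.  The bias starts at 0.5 so initial predictions sit
    mid-window.
    """

    def __init__(self, in_channels: int, n_outputs: int, rng: np.random.Generator,
                 output_scale: float = 250.0):
        super().__init__()
        self.fc = Linear(in_channels, n_outputs, rng, weight_scale=0.01, bias_init=0.5)
        self.output_scale = output_scale

    def forward(self, x: Tensor) -> Tensor:
        return self.fc(global_avg_pool(x)).relu() * self.output_scale


def se_bottleneck_width(channels: int, reduction_ratio: int) -> int:
    """Excitation bottleneck width: round(C / r), at least 1."""
    return max(1, int(round(channels / reduction_ratio)))


class ChannelSE(Module):
    """Channel squeeze-and-excitation (cSE).

    Squeeze: per-channel global average over positions.  Excite: two fully
    connected layers with a C/r bottleneck — inner ReLU, outer sigmoid — give
    per-channel gates in (0, 1) that rescale the channels.
    """

    def __init__(self, channels: int, reduction_ratio: int, rng: np.random.Generator):
        super().__init__()
        hidden = se_bottleneck_width(channels, reduction_ratio)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def gates(self, x: Tensor) -> Tensor:
        z = global_avg_pool(x)  # (N, C)
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return x * self.gates(x).reshape(n, c, 1)


class SpatialSE(Module):
    """Spatial squeeze-and-excitation (sSE).

    A kernel-1 convolution collapses the channels to one logit per position;
    its sigmoid gates every channel at that position.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv1d(channels, 1, 1, rng)

    def gates(self, x: Tensor) -> Tensor:
        return self.conv(x).sigmoid()  # (N, 1, W)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gates(x)


class ConcurrentSE(Module):
    """Concurrent spatial and channel SE (scSE): combine cSE and sSE outputs.

    The element-wise combination defaults to maximum; "sum" is also supported.
    """

    def __init__(self, channels: int, reduction_ratio: int, rng: np.random.Generator,
                 combine: str = "max"):
        super().__init__()
        if combine not in ("max", "sum"):
            raise ValueError("combine must be 'max' or 'sum'")
        self.cse = ChannelSE(channels, reduction_ratio, rng)
        self.sse = SpatialSE(channels, rng)
        self.combine = combine

    def forward(self, x: Tensor) -> Tensor:
        a, b = self.cse(x), self.sse(x)
        return maximum(a, b) if self.combine == "max" else a + b


def make_se_block(variant: str, channels: int, reduction_ratio: int,
                  rng: np.random.Generator, combine: str = "max") -> Module | None:
    """SE block factory; returns None for variant 'none'."""
    if variant == "none":
        return None
    if variant == "cSE":
        return ChannelSE(channels, reduction_ratio, rng)
    if variant == "sSE":
        return SpatialSE(channels, rng)
    if variant == "scSE":
        return ConcurrentSE(channels, reduction_ratio, rng, combine=combine)
    raise ValueError(f"unknown SE variant: {variant!r}")
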