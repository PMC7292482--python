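"""Neural-network layers for 1D signals: conv, batch norm, linear, pooling.

Feature maps are laid out ``(batch, channels, length)``.  Convolutions use
"same" zero padding so densely-concatenated feature maps stay aligned.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Conv1d",
    "Linear",
    "BatchNorm1d",
    "avg_pool1d",
    "global_avg_pool",
]


class Module:
    """Tiny module base: parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _modules(self) -> list["Module"]:
        mods = []
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.append(value)
            elif isinstance(value, (list, tuple)):
                mods.extend(v for v in value if isinstance(v, Module))
        return mods

    def train(self) -> "Module":
        self.training = True
        for m in self._modules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._modules():
            m.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # state (de)serialization -------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable and running arrays, in deterministic traversal order."""
        arrays: list[np.ndarray] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                arrays.append(value.data)
            elif isinstance(value, Module):
                arrays.extend(value.state_arrays())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        arrays.extend(item.state_arrays())
        if isinstance(self, BatchNorm1d):
            arrays.extend([self.running_mean, self.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        self._load_from_iter(it)
        try:
            next(it)
        except StopIteration:
            return
        raise ValueError("state has more arrays than the model expects")

    def _load_from_iter(self, it) -> None:
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                arr = np.asarray(next(it), dtype=np.float64)
                if arr.shape != value.data.shape:
                    raise ValueError("state array shape mismatch")
                value.data = arr
            elif isinstance(value, Module):
                value._load_from_iter(it)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._load_from_iter(it)
        if isinstance(self, BatchNorm1d):
            self.running_mean = np.asarray(next(it), dtype=np.float64)
            self.running_var = np.asarray(next(it), dtype=np.float64)


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Module):
    """1D convolution with "same" zero padding (stride 1)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        self.weight = Tensor(
            _he_normal(rng, (out_channels, in_channels, kernel_size), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        k = self.kernel_size
        pad = k // 2
        n, c_in, width = x.shape
        if pad:
            xp = np.empty((n, c_in, width + 2 * pad))
            xp[:, :, :pad] = 0.0
            xp[:, :, -pad:] = 0.0
            xp[:, :, pad:pad + width] = x.data
        else:
            xp = x.data
        # conv as a sum of per-offset channel matmuls: (O,C) @ (N,C,W) -> (N,O,W)
        out = np.matmul(w.data[:, :, 0], xp[:, :, 0:width])
        for j in range(1, k):
            out += np.matmul(w.data[:, :, j], xp[:, :, j:j + width])
        out += b.data[None, :, None]

        def backward(g):
            gw = np.empty_like(w.data)
            for j in range(k):
                gw[:, :, j] = np.matmul(
                    g, xp[:, :, j:j + width].transpose(0, 2, 1)
                ).sum(axis=0)
            gb = g.sum(axis=(0, 2))
            wt = w.data.transpose(2, 1, 0)  # (K, C, O)
            if pad:
                gxp = np.zeros((n, c_in, width + 2 * pad))
                for j in range(k):
                    gxp[:, :, j:j + width] += np.matmul(wt[j], g)
                gx = gxp[:, :, pad:pad + width]
            else:
                gx = np.matmul(wt[0], g)
                for j in range(1, k):
                    gx += np.matmul(wt[j], g)
            return (gx, gw, gb)

        return Tensor._make(out, (x, w, b), backward)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 weight_scale: float | None = None, bias_init: float = 0.0):
        super().__init__()
        if weight_scale is None:
            w = _he_normal(rng, (in_features, out_features), in_features)
        else:
            w = rng.normal(0.0, weight_scale, size=(in_features, out_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.full(out_features, float(bias_init)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalization over (batch, length) per channel.

    Accepts ``(N, C, W)`` or ``(N, C)`` input.  Training mode uses batch
    statistics and updates exponential running averages (momentum 0.9);
    eval mode uses the running averages.
    """

    def __init__(self, num_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_channels), requires_grad=True)
        self.beta = Tensor(np.zeros(num_channels), requires_grad=True)
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return self._forward(x, spatial=x.ndim == 3)

    def _forward(self, x: Tensor, spatial: bool) -> Tensor:
        axes = (0, 2) if spatial else (0,)
        shape = (1, -1, 1) if spatial else (1, -1)
        gamma, beta = self.gamma, self.beta
        if self.training:
            # single-pass moments: E[x], E[x^2]
            mean = x.data.mean(axis=axes)
            var = (x.data ** 2).mean(axis=axes) - mean**2
            np.maximum(var, 0.0, out=var)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        # fused affine: out = a * x + bias_term
        a = gamma.data * inv_std
        out = x.data * a.reshape(shape)
        out += (beta.data - a * mean).reshape(shape)
        m = x.data.size / gamma.data.size
        use_batch_stats = self.training

        def backward(g):
            xhat = x.data - mean.reshape(shape)
            xhat *= inv_std.reshape(shape)
            sub = "ncw,ncw->c" if xhat.ndim == 3 else "nc,nc->c"
            ggamma = np.einsum(sub, g, xhat)
            gbeta = g.sum(axis=axes)
            if use_batch_stats:
                # gx = gamma*inv_std/m * (m*g - gbeta - xhat*ggamma), per channel
                gx = g * m
                gx -= gbeta.reshape(shape)
                xhat *= ggamma.reshape(shape)
                gx -= xhat
                gx *= (gamma.data * inv_std / m).reshape(shape)
            else:
                gx = g * (gamma.data * inv_std).reshape(shape)
            return (gx, ggamma, gbeta)

        return Tensor._make(out, (x, gamma, beta), backward)


def avg_pool1d(x: Tensor, size: int = 2, stride: int | None = None) -> Tensor:
    """Average pooling; output length floor(W / size) (trailing remainder dropped)."""
    if stride is not None and stride != size:
        raise NotImplementedError("only stride == size pooling is supported")
    n, c, width = x.shape
    w_out = width // size
    trimmed = x.data[:, :, : w_out * size]
    out = trimmed.reshape(n, c, w_out, size).mean(axis=3)

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[:, :, : w_out * size] = np.repeat(g, size, axis=2) / size
        return (gx,)

    return Tensor._make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the length axis: (N, C, W) -> (N, C)."""
    return x.mean(axis=2)
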